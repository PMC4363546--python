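# Methods

## Model

`indirank` treats indication prediction as multi-label ranking by weighted
k-nearest neighbors. For a query drug *d_q* and each indication tag *D_j*,
the score is the sum of the *k* largest pairwise weights between the query
and the training drugs carrying *D_j*; when the category holds fewer than
*k* drugs, all are summed. Setting *k* = 1 gives nearest-neighbor scoring;
*k* = n (the training size) gives the full category sum — both limits are
asserted in the test suite. A training drug with several tags is an
eligible neighbor for each of its tags independently.

Two weight functions are combined **sequentially**: interaction confidence
(*k* = 5) first, and only if every tag scores zero — the query has no
interactive partner in training — Tanimoto similarity between ECFP_4
fingerprints (*k* = 2). The rationale for the ordering is that a curated
interaction score already aggregates structural, experimental and
literature evidence, so it dominates raw structural similarity when
available; the similarity channel exists to say *something* about the
large fraction of drugs missing from interaction databases. The
alternative **averaged** integration scores each tag as
(R^i + R^s)/2 up front; for drugs without interaction partners it provably
reproduces the sequential (similarity) ranking with halved scores, a
property tested exactly.

Only strictly positive scores are ranked. A drug can therefore receive
fewer ranked predictions than the reporting depth *t*; missing orders
count as incorrect, i.e. the accuracy denominator is always the full
sample count. Ties are broken by catalog order — a strict ordering is
assumed by the method's definition and a deterministic rule is mandatory
for reproducible evaluation; any other fixed rule would shift accuracies
only marginally.

The query's own record is always removed from training before scoring:
self-similarity of 1.0 would otherwise dominate every similarity score.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k_interaction` | 5 | neighbors summed on the interaction channel |
| `k_similarity` | 2 | neighbors summed on the similarity channel |
| fingerprint | ECFP_4, 2048 bits | circular fingerprint, diameter 4 (radius 2) |
| interaction scale | 1000 | divisor turning STITCH integer scores into [0,1] weights |
| dedup threshold | 0.7 | Tanimoto at/above which two drugs count as near-duplicates |
| min category size | 8 | categories below this are dropped during curation |

The k defaults are the operating point found by leave-one-out tuning on
the reference corpus this method was developed against; they are
configurable everywhere. Score scaling by 1000 fixes reported magnitudes
only — top-k ranking is scale-invariant. The 2048-bit folding length is
the de-facto standard; rankings can shift slightly with folding. MACCS is
fixed at 166 keys. The "PATH" family (hashed linear paths up to 7 bonds)
approximates Open Babel's FP2 and is excluded from default benchmarks.
No salt stripping or standardization is applied by default; a
largest-fragment helper exists, off by default.

## Curation

Corpus construction applies, in order: (1) iterative removal of
indication categories with fewer than 8 members, dropping drugs left
tagless (tag removal can never shrink another category — a drug dropped
with its last tag contributed to no other — so one sweep over tags
converges; the drug-removal step is still re-checked); (2) near-duplicate
removal by a maximal independent set of the graph whose edges join pairs
with similarity ≥ 0.7. *Maximal* (not maximum) suffices for the stated
purpose — no retained pair at or above the threshold, and every removed
drug keeps a retained neighbor. The greedy runs over a static
ascending-degree order with dataset-order tie-breaks: deterministic, and
biased toward larger sets. The `seed` argument is reserved for a
randomized variant and unused by the default.

## Evaluation

ACC_i is the fraction of all evaluated drugs whose i-th ranked tag is
true; short or empty rankings stay in the denominator. Recall_t and
Precision_t average per-drug correct-in-top-t over the true-label count
and over t respectively; ACC_1 = Precision_1 identically, asserted on
every run. The reporting depth is t = ⌈Average⌉ where Average is the mean
label count. Per-category sensitivity uses the first two ranks by
default; its Pearson correlation with relative category size is reported
to expose category-size bias (undefined — reported as null — when
sensitivities are constant).

The jackknife (leave-one-out) is fully deterministic. Repeated k-fold
uses uniform random unstratified partitions with fold sizes differing by
at most one, driven by `(seed, repeat)`; means and sample (n−1) standard
deviations are reported across repeats. Stratification is deliberately
not applied (the protocol being mirrored does not use it). With
folds = n, one repeat reproduces the jackknife exactly (tested).

## Synthetic corpus

The generator emulates exactly the statistics the method exploits, and
nothing else:

* label counts 1/2/3 with probabilities 0.77/0.20/0.03 (≈1.26 labels per
  drug, matching the ~1.27 of the reference corpus);
* Zipf-like category weights (exponent 0.7) giving a few large and many
  small categories;
* per-category random bit prototypes (40 of 256 bits); a drug's
  fingerprint is the union of its categories' prototypes with per-bit
  flip probability `bit_noise` (default 0.05) — at zero noise
  within-category Tanimoto is exactly 1;
* interaction edges at density 0.15 between same-tag pairs vs 0.01 across,
  with scores Beta(8,2) vs Beta(2,8), but only among the 57% of drugs
  designated "covered": real interaction databases miss a large fraction
  of drugs, and it is precisely the uncovered drugs that exercise the
  similarity fallback. Without this, essentially every drug takes the
  interaction path and structural noise has no visible effect on the
  integrated predictor.

What it does **not** emulate: real chemistry (no synthetic SMILES —
similarity is consumed as a pairwise function, so bit vectors suffice;
the chemistry module is tested end-to-end on a small list of real SMILES
instead), evidence-channel decomposition of interaction scores,
correlated label co-occurrence structure, or realistic similarity
distributions between unrelated drugs. Passing benchmarks on this corpus
therefore demonstrates that the implementation recovers planted signal
and respects the protocol — not that the method attains any particular
accuracy on real pharmacopoeias.

One subtlety the tests document: with skewed category sizes, a top-k-sum
scorer carries a category-size prior and beats a uniform random-permutation
null even with zero pairwise signal (bigger categories offer more chances
for spurious partners *and* are more likely a priori). The nil-signal
check therefore uses uniform category weights; the skewed default is kept
for realism.

## Numerical choices and degenerate inputs

* Tanimoto of two all-zero vectors is 0 by convention; self-similarity is
  1 only for drugs inside a provider's support.
* Drugs with unparseable SMILES go to a skipped-set and report similarity
  0 everywhere rather than aborting a batch run.
* Interaction lookups are total: absent pair ⇒ exactly 0.0; stored scores
  must lie in (0, 1]; duplicate pair rows (either order) — last wins with
  a warning.
* Identifier matching is exact string equality; a CID zero-padding
  normalizer is provided but never applied implicitly.
* Pearson correlation on a constant vector raises (zero denominator).
* Malformed input rows raise errors naming the line; nothing is silently
  repaired.

## Problem sizes

The default benchmark is 200 drugs × 10 categories, jackknifed in well
under a second; acceptance-style sweeps use 10 replicate seeds at four
noise levels, and the Monte-Carlo null uses a 1,573-drug, 56-category
corpus with 20 permutation replicates. These sizes put Monte-Carlo error
well below the margins being asserted while keeping any single check in
the seconds range.

## Known limitations

* The interaction and similarity channels are combined by a fixed rule;
  no weights are learned and scores are not calibrated probabilities.
* Disease-side (disease-centric) prediction, 3D similarity, and AUROC-type
  threshold-free metrics are out of scope.
* The near-duplicate independent set is maximal, not maximum; a different
  (still valid) set — hence slightly different downstream accuracies —
  would result from another traversal order.
* Bit-exact reproduction of any particular external fingerprint
  implementation (e.g. Open Babel FP2) is not attempted.
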
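"""Dataset curation: small-category filtering and near-duplicate removal.

Two procedures, applied in this order when building a benchmark corpus:

1. drop indication categories with fewer than ``min_size`` members (too
   small to score meaningfully), then drop drugs left without any tag,
   iterating to a fixed point;
2. remove near-duplicate structures by taking a maximal independent set of
   the similarity graph whose edges join drug pairs with Tanimoto >= 0.7 —
   structural analogues of the same parent drug are trivially easy to
   predict and would inflate every accuracy figure.

Any maximal independent set guarantees the retained set has no pair at or
above the threshold and that every removed drug has a retained neighbor
(so removal loses no structural neighborhood entirely).  The greedy
ascending-degree heuristic is used because it is deterministic and tends
toward large sets; maximum cardinality is not required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem_similarity import SimilarityProvider
from .dataio import Dataset, DrugRecord

__all__ = ["CurationReport", "filter_small_categories", "dedup_max_independent_set"]


@dataclass
class CurationReport:
    """What a curation stage removed and what remains."""

    removed_small_category_tags: list[str] = field(default_factory=list)
    removed_drug_ids: list[str] = field(default_factory=list)
    retained_count: int = 0
    sizes_before: dict[str, int] = field(default_factory=dict)
    sizes_after: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "removed_small_category_tags": self.removed_small_category_tags,
            "removed_drug_ids": self.removed_drug_ids,
            "retained_count": self.retained_count,
            "sizes_before": self.sizes_before,
            "sizes_after": self.sizes_after,
        }


def filter_small_categories(
    dataset: Dataset, min_size: int = 8
) -> tuple[Dataset, CurationReport]:
    """Remove categories with fewer than *min_size* members.

    Removing a tag shrinks some drugs' label sets; drugs left with no tags
    are dropped, which can in turn shrink other categories, so the
    tag-removal / drug-removal cycle iterates until a fixed point.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    report = CurationReport(sizes_before=dataset.category_sizes())
    drugs = list(dataset.drugs)
    tags = list(dataset.catalog.tags)
    removed_tags: list[str] = []
    while True:
        sizes: dict[str, int] = {t: 0 for t in tags}
        for d in drugs:
            for t in d.indications:
                if t in sizes:
                    sizes[t] += 1
        too_small = [t for t in tags if sizes[t] < min_size]
        if not too_small:
            break
        removed_tags.extend(too_small)
        keep = set(tags) - set(too_small)
        tags = [t for t in tags if t in keep]
        new_drugs: list[DrugRecord] = []
        for d in drugs:
            remaining = d.indications & keep
            if remaining:
                new_drugs.append(DrugRecord(d.drug_id, d.smiles, frozenset(remaining)))
            else:
                report.removed_drug_ids.append(d.drug_id)
        drugs = new_drugs
    curated = Dataset(dataset.catalog.restrict(tags), drugs)
    report.removed_small_category_tags = removed_tags
    report.retained_count = len(drugs)
    report.sizes_after = curated.category_sizes()
    return curated, report


def dedup_max_independent_set(
    dataset: Dataset,
    similarity: SimilarityProvider,
    threshold: float = 0.7,
    seed: int | None = None,
) -> tuple[Dataset, CurationReport]:
    """Drop near-duplicates: keep a maximal independent set of the
    similarity graph with edges where similarity >= *threshold*.

    Greedy by ascending degree, ties broken by dataset order; *seed* is
    reserved for a randomized variant and unused by the deterministic
    default.  The result satisfies (a) every retained pair has similarity
    below the threshold, and (b) maximality — every removed drug is at or
    above the threshold to at least one retained drug.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ids = dataset.drug_ids
    n = len(ids)
    adj: dict[str, set[str]] = {i: set() for i in ids}
    for i in range(n):
        for j in range(i + 1, n):
            if similarity.get(ids[i], ids[j]) >= threshold:
                adj[ids[i]].add(ids[j])
                adj[ids[j]].add(ids[i])
    order = sorted(range(n), key=lambda i: (len(adj[ids[i]]), i))
    retained: set[str] = set()
    for i in order:
        if not (adj[ids[i]] & retained):
            retained.add(ids[i])
    report = CurationReport(
        removed_drug_ids=[i for i in ids if i not in retained],
        retained_count=len(retained),
        sizes_before=dataset.category_sizes(),
    )
    curated = dataset.subset(retained)
    report.sizes_after = curated.category_sizes()
    return curated, report
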
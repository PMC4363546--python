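"""Top-k weighted-neighbor scoring and indication ranking.

The score that a query drug has indication D_j is the sum of the k largest
pairwise weights between the query and the training drugs tagged D_j:

    R(d_q => D_j) = sum of top-k { w(d_q, d) : d in training, D_j in tags(d) }

with the weight function w being either interaction confidence (w^i, k = 5
by default) or fingerprint Tanimoto similarity (w^s, k = 2 by default).
When a category holds fewer than k drugs, all of them are summed.  k = 1
reduces to nearest-neighbor scoring; k = n (the training-set size) to the
full category sum.

Candidate indications are ranked by descending score; only strictly
positive scores are ranked (a zero score means "no evidence"), so the
ranking may be empty — the trivial outcome when the query has no
interaction partner or no similar structure in training.  Ties are broken
by catalog order, a deterministic rule the strict-ordering definition
leaves open.

Two ways of combining the evidence sources:

* **sequential** — rank by interaction confidence; only if that ranking is
  empty, fall back to similarity.
* **averaged scores** — per tag, (R^i + R^s) / 2 computed up front, then
  ranked once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .chem_similarity import FingerprintSpec, SimilarityProvider
from .dataio import Dataset, IndicationCatalog, InteractionTable

__all__ = [
    "RankedPrediction",
    "PredictorConfig",
    "score_by_weights",
    "rank_indications",
    "predict_integrated",
    "predict_integrated_scores",
]

WeightFn = Callable[[str, str], float]


@dataclass(frozen=True)
class RankedPrediction:
    """Strictly ordered candidate indications for one query drug.

    ``items`` is a list of (tag, score) with scores non-increasing and
    strictly positive; position 0 is the 1st order prediction, position 1
    the 2nd, and so on.  ``provenance`` records which evidence source
    produced the ranking.
    """

    items: tuple[tuple[str, float], ...] = ()
    provenance: str = "interaction"

    def __post_init__(self) -> None:
        if self.provenance not in ("interaction", "similarity", "integrated_score"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        tags = [t for t, _ in self.items]
        if len(set(tags)) != len(tags):
            raise ValueError("duplicate tags in ranking")
        scores = [s for _, s in self.items]
        if any(s <= 0 for s in scores):
            raise ValueError("ranked scores must be strictly positive")
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise ValueError("ranked scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.items)

    def __bool__(self) -> bool:
        return bool(self.items)

    @property
    def tags(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.items)

    def order(self, i: int) -> str | None:
        """The i-th order predicted tag (1-based), or None when the ranking
        is shorter than i."""
        if i < 1:
            raise ValueError("order is 1-based")
        return self.items[i - 1][0] if i <= len(self.items) else None


@dataclass(frozen=True)
class PredictorConfig:
    """Neighborhood sizes and fingerprint choice.

    Defaults are the operating point selected by leave-one-out tuning on
    the reference corpus: k = 5 neighbors for interaction confidence,
    k = 2 with ECFP_4 for structural similarity.
    """

    k_interaction: int = 5
    k_similarity: int = 2
    fingerprint: FingerprintSpec = field(default_factory=lambda: FingerprintSpec("ECFP", 4))

    def __post_init__(self) -> None:
        if self.k_interaction < 1 or self.k_similarity < 1:
            raise ValueError("neighborhood sizes must be >= 1")


def score_by_weights(
    query: str, tag: str, training: Dataset, weight: WeightFn, k: int
) -> float:
    """Sum of the k largest weights from *query* to training drugs tagged *tag*.

    The caller is responsible for excluding the query's own record from
    *training* (leave-one-out); a self-weight of 1 would dominate any
    similarity-based score.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    members = training.members(tag)  # raises KeyError for an unknown tag
    weights = sorted((weight(query, d) for d in members), reverse=True)
    return float(sum(weights[:k]))


def rank_indications(
    query: str,
    training: Dataset,
    weight: WeightFn,
    k: int,
    catalog: IndicationCatalog | None = None,
    provenance: str = "interaction",
) -> RankedPrediction:
    """Score every catalog tag and rank those with positive score.

    Descending score, ties broken by ascending catalog index.  Returns an
    empty ranking iff every tag scores zero.
    """
    cat = catalog if catalog is not None else training.catalog
    scored = []
    for idx, tag in enumerate(cat.tags):
        s = score_by_weights(query, tag, training, weight, k)
        if s > 0.0:
            scored.append((-s, idx, tag, s))
    scored.sort()
    return RankedPrediction(
        items=tuple((tag, s) for _, _, tag, s in scored), provenance=provenance
    )


def predict_integrated(
    query: str,
    training: Dataset,
    interactions: InteractionTable,
    similarity: SimilarityProvider,
    config: PredictorConfig = PredictorConfig(),
) -> RankedPrediction:
    """Sequential integration: interaction ranking, similarity as fallback.

    The similarity path fires iff the interaction ranking is empty, i.e.
    the query has no interactive training partner sharing any tag.
    """
    by_int = rank_indications(
        query, training, interactions.get, config.k_interaction,
        provenance="interaction",
    )
    if by_int:
        return by_int
    return rank_indications(
        query, training, similarity.get, config.k_similarity,
        provenance="similarity",
    )


def predict_integrated_scores(
    query: str,
    training: Dataset,
    interactions: InteractionTable,
    similarity: SimilarityProvider,
    config: PredictorConfig = PredictorConfig(),
) -> RankedPrediction:
    """Averaged-score integration: per tag, (R^i + R^s) / 2, ranked once.

    For a query with no interaction partners this reproduces the
    similarity-only ranking with every score halved.
    """
    cat = training.catalog
    scored = []
    for idx, tag in enumerate(cat.tags):
        ri = score_by_weights(query, tag, training, interactions.get, config.k_interaction)
        rs = score_by_weights(query, tag, training, similarity.get, config.k_similarity)
        s = (ri + rs) / 2.0
        if s > 0.0:
            scored.append((-s, idx, tag, s))
    scored.sort()
    return RankedPrediction(
        items=tuple((tag, s) for _, _, tag, s in scored), provenance="integrated_score"
    )
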
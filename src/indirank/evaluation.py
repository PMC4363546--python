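"""Cross-validation harnesses and ranking metrics.

Each evaluated drug receives a ranked list of candidate indications; the
metrics ask how far down that list its true indications sit.

* **i-th order accuracy** ACC_i = PD_i / N: the fraction of all N evaluated
  drugs whose i-th ranked tag is a true indication.  Drugs whose ranking is
  shorter than i (including empty rankings) stay in the denominator and
  contribute nothing to PD_i.
* **Recall_t / Precision_t**: per-drug correct-in-top-t divided by the
  drug's true-label count, respectively by t, each averaged over drugs.
  ACC_1 = Precision_1 identically.
* **Average / t**: mean number of true labels per drug; t = ceil(Average)
  is the natural reporting depth for recall and precision.
* **per-category sensitivity** SN_i: of the drugs truly carrying tag i, the
  fraction that retrieve it within their first ``top`` predictions.
* **Pearson r** between per-category sensitivity and relative category
  size, to check whether the ranking merely favors big categories.

Two harnesses: the jackknife (leave-one-out — deterministic, every drug
predicted with itself removed from training) and repeated k-fold
cross-validation (unstratified uniform random partition, seeded; metrics
reported per repeat with mean and sample standard deviation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .chem_similarity import SimilarityProvider
from .dataio import Dataset, IndicationCatalog, InteractionTable
from .predictor import (
    PredictorConfig,
    RankedPrediction,
    predict_integrated,
    predict_integrated_scores,
    rank_indications,
)

__all__ = [
    "EvaluationReport",
    "order_accuracy",
    "recall_precision_at_t",
    "average_labels",
    "per_category_sn",
    "pearson_r",
    "predict_all",
    "jackknife",
    "kfold",
    "MODES",
]

MODES = ("sequential", "averaged", "interaction", "similarity")

Predictions = Mapping[str, RankedPrediction]
Truth = Mapping[str, frozenset[str]]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def order_accuracy(predictions: Predictions, truth: Truth, i: int) -> float:
    """ACC_i: fraction of drugs whose i-th order prediction is correct."""
    if i < 1:
        raise ValueError("order i must be >= 1")
    if not truth:
        raise ValueError("empty truth")
    hits = 0
    for drug_id, labels in truth.items():
        pred = predictions.get(drug_id)
        tag = pred.order(i) if pred is not None else None
        if tag is not None and tag in labels:
            hits += 1
    return hits / len(truth)


def recall_precision_at_t(
    predictions: Predictions, truth: Truth, t: int
) -> tuple[float, float]:
    """(Recall_t, Precision_t) over the first t ranked predictions.

    A ranking shorter than t contributes only its ranked tags to the
    correct count; the precision denominator stays t for every drug.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if not truth:
        raise ValueError("empty truth")
    recall = precision = 0.0
    for drug_id, labels in truth.items():
        pred = predictions.get(drug_id)
        top = pred.tags[:t] if pred is not None else ()
        correct = sum(1 for tag in top if tag in labels)
        recall += correct / len(labels)
        precision += correct / t
    n = len(truth)
    return recall / n, precision / n


def average_labels(truth: Truth) -> tuple[float, int]:
    """(Average, t): mean true-label count and its ceiling."""
    if not truth:
        raise ValueError("empty truth")
    avg = sum(len(v) for v in truth.values()) / len(truth)
    return avg, math.ceil(avg)


def per_category_sn(
    predictions: Predictions,
    truth: Truth,
    catalog: IndicationCatalog,
    top: int = 2,
) -> dict[str, float]:
    """SN_i = TP_i / C_i per category; categories with no member are absent.

    C_i counts the drugs truly tagged with tag i, TP_i those of them whose
    first *top* ranked tags include it.
    """
    if top < 1:
        raise ValueError("top must be >= 1")
    c = {tag: 0 for tag in catalog.tags}
    tp = {tag: 0 for tag in catalog.tags}
    for drug_id, labels in truth.items():
        pred = predictions.get(drug_id)
        head = set(pred.tags[:top]) if pred is not None else set()
        for tag in labels:
            c[tag] += 1
            if tag in head:
                tp[tag] += 1
    return {tag: tp[tag] / c[tag] for tag in catalog.tags if c[tag] > 0}


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = math.sqrt(float(dx @ dx) * float(dy @ dy))
    if denom == 0.0:
        raise ValueError("constant vector: correlation undefined")
    return float(dx @ dy) / denom


# ---------------------------------------------------------------------------
# harnesses
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Aggregated metrics for one evaluation run.

    ``acc`` holds one ACC vector (ACC_1 … ACC_m, m = catalog size) per
    repeat; the jackknife is a single "repeat".  Standard deviations use
    the sample (n-1) convention and are None when there is one repeat.
    """

    scheme: str
    mode: str
    n_samples: int
    n_categories: int
    acc: list[list[float]]
    recall_t: list[float]
    precision_t: list[float]
    average_labels: float
    t: int
    per_category_sn: dict[str, list[float]]
    pearson_r: float | None
    seed: int | None = None
    folds: int | None = None

    @staticmethod
    def _mean_std(rows: list[list[float]]) -> tuple[list[float], list[float] | None]:
        arr = np.asarray(rows, dtype=float)
        mean = arr.mean(axis=0).tolist()
        std = arr.std(axis=0, ddof=1).tolist() if arr.shape[0] > 1 else None
        return mean, std

    @property
    def acc_mean(self) -> list[float]:
        return self._mean_std(self.acc)[0]

    @property
    def acc_std(self) -> list[float] | None:
        return self._mean_std(self.acc)[1]

    @property
    def sn_mean(self) -> dict[str, float]:
        return {tag: float(np.mean(v)) for tag, v in self.per_category_sn.items()}

    def to_dict(self) -> dict:
        def scalar_stats(vals: list[float]):
            return {
                "per_repeat": vals,
                "mean": float(np.mean(vals)),
                "std": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
            }

        return {
            "schema_version": 1,
            "scheme": self.scheme,
            "mode": self.mode,
            "seed": self.seed,
            "folds": self.folds,
            "n_samples": self.n_samples,
            "n_categories": self.n_categories,
            "average_labels": self.average_labels,
            "t": self.t,
            "acc": {"per_repeat": self.acc, "mean": self.acc_mean, "std": self.acc_std},
            "recall_t": scalar_stats(self.recall_t),
            "precision_t": scalar_stats(self.precision_t),
            "per_category_sn": {
                "per_repeat": self.per_category_sn,
                "mean": self.sn_mean,
            },
            "pearson_r": self.pearson_r,
        }


def _predict_one(
    query: str,
    training: Dataset,
    interactions: InteractionTable,
    similarity: SimilarityProvider,
    config: PredictorConfig,
    mode: str,
) -> RankedPrediction:
    if mode == "sequential":
        return predict_integrated(query, training, interactions, similarity, config)
    if mode == "averaged":
        return predict_integrated_scores(query, training, interactions, similarity, config)
    if mode == "interaction":
        return rank_indications(
            query, training, interactions.get, config.k_interaction,
            provenance="interaction",
        )
    if mode == "similarity":
        return rank_indications(
            query, training, similarity.get, config.k_similarity,
            provenance="similarity",
        )
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def predict_all(
    test_ids: list[str],
    training: Dataset,
    interactions: InteractionTable,
    similarity: SimilarityProvider,
    config: PredictorConfig,
    mode: str = "sequential",
) -> dict[str, RankedPrediction]:
    """Predict each test drug against a fixed training set."""
    return {
        q: _predict_one(q, training, interactions, similarity, config, mode)
        for q in test_ids
    }


def _metrics_for_run(
    predictions: Predictions, dataset: Dataset, top: int
) -> tuple[list[float], float, float, dict[str, float], float, int]:
    truth = dataset.truth()
    m = len(dataset.catalog)
    avg, t = average_labels(truth)
    acc = [order_accuracy(predictions, truth, i) for i in range(1, m + 1)]
    recall, precision = recall_precision_at_t(predictions, truth, t)
    sn = per_category_sn(predictions, truth, dataset.catalog, top=top)
    return acc, recall, precision, sn, avg, t


def _sn_size_correlation(
    sn_per_repeat: dict[str, list[float]], dataset: Dataset
) -> float | None:
    sizes = dataset.category_sizes()
    tags = sorted(sn_per_repeat, key=dataset.catalog.index)
    if len(tags) < 2:
        return None
    total = sum(sizes[t] for t in tags)
    x = [float(np.mean(sn_per_repeat[t])) for t in tags]
    y = [sizes[t] / total for t in tags]
    try:
        return pearson_r(x, y)
    except ValueError:  # constant sensitivities — correlation undefined
        return None


def jackknife(
    dataset: Dataset,
    interactions: InteractionTable,
    similarity: SimilarityProvider,
    config: PredictorConfig = PredictorConfig(),
    mode: str = "sequential",
    sn_top: int = 2,
) -> EvaluationReport:
    """Leave-one-out evaluation: each drug predicted with itself removed.

    Fully deterministic — training and test splits are fixed by the data.
    Removing a drug from training removes it as a candidate neighbor; the
    interaction table itself is pairwise, so no other entry changes.
    """
    if len(dataset) < 2:
        raise ValueError("jackknife needs at least 2 drugs")
    predictions: dict[str, RankedPrediction] = {}
    for d in dataset:
        training = dataset.without(d.drug_id)
        predictions[d.drug_id] = _predict_one(
            d.drug_id, training, interactions, similarity, config, mode
        )
    acc, recall, precision, sn, avg, t = _metrics_for_run(predictions, dataset, sn_top)
    sn_per_repeat = {tag: [v] for tag, v in sn.items()}
    return EvaluationReport(
        scheme="jackknife",
        mode=mode,
        n_samples=len(dataset),
        n_categories=len(dataset.catalog),
        acc=[acc],
        recall_t=[recall],
        precision_t=[precision],
        average_labels=avg,
        t=t,
        per_category_sn=sn_per_repeat,
        pearson_r=_sn_size_correlation(sn_per_repeat, dataset),
    )


def _partition(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Uniform random unstratified split into near-equal parts (sizes differ
    by at most 1)."""
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def kfold(
    dataset: Dataset,
    interactions: InteractionTable,
    similarity: SimilarityProvider,
    config: PredictorConfig = PredictorConfig(),
    mode: str = "sequential",
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    sn_top: int = 2,
) -> EvaluationReport:
    """Repeated k-fold cross-validation.

    Each repeat partitions the drugs uniformly at random (no
    stratification) into *folds* near-equal parts; each part is predicted
    with the union of the others as training.  The partition stream is
    driven by (seed, repeat index), so runs are reproducible and repeats
    are independent.  With folds == len(dataset) a single repeat is the
    jackknife.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(dataset) < folds:
        raise ValueError("dataset smaller than fold count")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    ids = dataset.drug_ids
    acc_rows: list[list[float]] = []
    recalls: list[float] = []
    precisions: list[float] = []
    sn_rows: list[dict[str, float]] = []
    avg = t = None
    for rep in range(repeats):
        rng = np.random.default_rng([seed, rep])
        predictions: dict[str, RankedPrediction] = {}
        for part in _partition(len(ids), folds, rng):
            test_ids = [ids[i] for i in part]
            training = dataset.subset(set(ids) - set(test_ids))
            predictions.update(
                predict_all(test_ids, training, interactions, similarity, config, mode)
            )
        acc, recall, precision, sn, avg, t = _metrics_for_run(
            predictions, dataset, sn_top
        )
        acc_rows.append(acc)
        recalls.append(recall)
        precisions.append(precision)
        sn_rows.append(sn)
    tags = sorted(set().union(*sn_rows), key=dataset.catalog.index) if sn_rows else []
    sn_per_repeat = {tag: [row[tag] for row in sn_rows] for tag in tags}
    return EvaluationReport(
        scheme="kfold",
        mode=mode,
        n_samples=len(dataset),
        n_categories=len(dataset.catalog),
        acc=acc_rows,
        recall_t=recalls,
        precision_t=precisions,
        average_labels=avg,
        t=t,
        per_category_sn=sn_per_repeat,
        pearson_r=_sn_size_correlation(sn_per_repeat, dataset),
        seed=seed,
        folds=folds,
    )
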
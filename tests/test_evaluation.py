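import math

import numpy as np
import pytest

from indirank import (
    InteractionTable,
    PredictorConfig,
    RankedPrediction,
    SimilarityProvider,
    average_labels,
    jackknife,
    kfold,
    order_accuracy,
    pearson_r,
    per_category_sn,
    recall_precision_at_t,
)
from indirank.dataio import IndicationCatalog
from conftest import make_dataset, random_fixture
from helpers_oracles import brute_jackknife_acc1, brute_sequential


def ranked(*tags_scores):
    return RankedPrediction(tuple(tags_scores))


class TestOrderAccuracy:
    def test_all_rank1_correct(self):
        truth = {"a": frozenset({"D_1"}), "b": frozenset({"D_2"})}
        preds = {"a": ranked(("D_1", 0.9)), "b": ranked(("D_2", 0.8))}
        assert order_accuracy(preds, truth, 1) == 1.0

    def test_hand_counted_half(self):
        truth = {d: frozenset({"D_1"}) for d in "abcd"}
        preds = {
            "a": ranked(("D_1", 0.9)),
            "b": ranked(("D_2", 0.9), ("D_1", 0.5)),
            "c": ranked(("D_1", 0.7)),
            "d": RankedPrediction(),
        }
        assert order_accuracy(preds, truth, 1) == pytest.approx(0.5)
        # short/empty rankings stay in the denominator at every order
        assert order_accuracy(preds, truth, 2) == pytest.approx(0.25)

    def test_empty_ranking_contributes_zero_everywhere(self):
        truth = {"a": frozenset({"D_1"})}
        preds = {"a": RankedPrediction()}
        for i in (1, 2, 5):
            assert order_accuracy(preds, truth, i) == 0.0

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            order_accuracy({}, {"a": frozenset({"D_1"})}, 0)


class TestRecallPrecision:
    def test_partial_credit_multilabel(self):
        truth = {"j": frozenset({"D_1", "D_2"})}
        preds = {"j": ranked(("D_1", 0.9), ("D_5", 0.3))}
        recall, precision = recall_precision_at_t(preds, truth, 2)
        assert recall == pytest.approx(0.5)
        assert precision == pytest.approx(0.5)

    def test_perfect_single_label_at_t1(self):
        truth = {"j": frozenset({"D_1"})}
        preds = {"j": ranked(("D_1", 0.9))}
        assert recall_precision_at_t(preds, truth, 1) == (1.0, 1.0)

    def test_precision_1_equals_acc_1(self):
        rng = np.random.default_rng(0)
        tags = [f"D_{i}" for i in range(1, 6)]
        truth = {f"d{j}": frozenset(rng.choice(tags, size=rng.integers(1, 3),
                                               replace=False))
                 for j in range(40)}
        preds = {}
        for d in truth:
            k = int(rng.integers(0, 4))
            chosen = rng.choice(tags, size=k, replace=False)
            scores = sorted(rng.uniform(0.1, 1.0, size=k), reverse=True)
            preds[d] = RankedPrediction(tuple(zip(chosen, scores)))
        _, p1 = recall_precision_at_t(preds, truth, 1)
        assert p1 == pytest.approx(order_accuracy(preds, truth, 1))

    def test_ranking_shorter_than_t(self):
        truth = {"j": frozenset({"D_1"})}
        preds = {"j": ranked(("D_1", 0.9))}
        recall, precision = recall_precision_at_t(preds, truth, 3)
        assert recall == 1.0
        assert precision == pytest.approx(1 / 3)


class TestAverageLabels:
    def test_mixed_counts(self):
        truth = {"a": frozenset({"D_1"}), "b": frozenset({"D_1"}),
                 "c": frozenset({"D_1", "D_2"})}
        avg, t = average_labels(truth)
        assert avg == pytest.approx(4 / 3)
        assert t == 2

    def test_all_single_label(self):
        truth = {d: frozenset({"D_1"}) for d in "abc"}
        assert average_labels(truth) == (1.0, 1)

    def test_reference_corpus_arithmetic(self):
        # 2,005 label memberships over 1,573 drugs: 1,209 singles, 313
        # doubles, 34 triples, 17 quadruples
        counts = [1] * 1209 + [2] * 313 + [3] * 34 + [4] * 17
        assert sum(counts) == 2005 and len(counts) == 1573
        truth = {f"d{i}": frozenset(f"D_{j}" for j in range(c))
                 for i, c in enumerate(counts)}
        avg, t = average_labels(truth)
        assert avg == pytest.approx(2005 / 1573)
        assert round(avg, 2) == 1.27
        assert t == 2

    def test_empty_truth_raises(self):
        with pytest.raises(ValueError):
            average_labels({})


class TestPerCategorySN:
    def test_hand_counted(self):
        cat = IndicationCatalog(["D_1", "D_2"])
        truth = {f"d{i}": frozenset({"D_1"}) for i in range(4)}
        preds = {
            "d0": ranked(("D_1", 0.9)),
            "d1": ranked(("D_2", 0.9), ("D_1", 0.5)),
            "d2": ranked(("D_1", 0.7)),
            "d3": ranked(("D_2", 0.9)),
        }
        sn = per_category_sn(preds, truth, cat, top=2)
        assert sn["D_1"] == pytest.approx(0.75)
        assert "D_2" not in sn  # no drug truly carries D_2

    def test_never_predicted_category_is_zero(self):
        cat = IndicationCatalog(["D_1"])
        truth = {"a": frozenset({"D_1"})}
        assert per_category_sn({"a": ranked(("D_1", 1.0))}, truth, cat)["D_1"] == 1.0
        assert per_category_sn({"a": RankedPrediction()}, truth, cat)["D_1"] == 0.0


class TestPearson:
    def test_exact_extremes(self):
        x = [1.0, 2.0, 5.0]
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed(self):
        # x=(1,2,3), y=(2,4,7): cov terms sum to 5, sum dx^2 = 2,
        # sum dy^2 = 114/9, so r = 5 / sqrt(2 * 114/9) = 0.993399...
        assert pearson_r([1, 2, 3], [2, 4, 7]) == pytest.approx(
            5 / math.sqrt(2 * 114 / 9), abs=1e-12)
        assert pearson_r([1, 2, 3], [2, 4, 7]) == pytest.approx(0.99339927, abs=1e-8)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestJackknife:
    def test_two_drug_mutual_partners(self):
        ds = make_dataset({"a": ["D_1"], "b": ["D_1"]})
        inter = InteractionTable({("a", "b"): 0.8})
        rep = jackknife(ds, inter, SimilarityProvider())
        assert rep.acc_mean[0] == 1.0
        assert rep.recall_t == [1.0]

    def test_no_evidence_gives_zero(self, toy_dataset):
        rep = jackknife(toy_dataset, InteractionTable(), SimilarityProvider())
        assert rep.acc_mean == [0.0] * 3

    def test_matches_leave_one_out_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            ds, inter, sim = random_fixture(rng, int(rng.integers(6, 20)),
                                            int(rng.integers(2, 6)))
            rep = jackknife(ds, inter, sim, PredictorConfig())
            expected = brute_jackknife_acc1(ds, inter, sim, 5, 2)
            assert rep.acc_mean[0] == pytest.approx(expected)

    def test_acc1_equals_precision1_identity(self):
        rng = np.random.default_rng(23)
        ds, inter, sim = random_fixture(rng, 15, 4)
        rep = jackknife(ds, inter, sim)
        preds = {
            d.drug_id: RankedPrediction(tuple(
                brute_sequential(d.drug_id, ds.without(d.drug_id), inter, sim, 5, 2)))
            for d in ds.drugs
        }
        _, p1 = recall_precision_at_t(preds, ds.truth(), 1)
        assert rep.acc_mean[0] == pytest.approx(p1)

    def test_too_small_dataset(self):
        ds = make_dataset({"a": ["D_1"]})
        with pytest.raises(ValueError):
            jackknife(ds, InteractionTable(), SimilarityProvider())


class TestKFold:
    def test_determinism_same_seed(self):
        rng = np.random.default_rng(31)
        ds, inter, sim = random_fixture(rng, 20, 4)
        r1 = kfold(ds, inter, sim, folds=4, repeats=3, seed=99)
        r2 = kfold(ds, inter, sim, folds=4, repeats=3, seed=99)
        assert r1.acc == r2.acc
        assert r1.recall_t == r2.recall_t

    def test_folds_equal_n_is_jackknife(self):
        rng = np.random.default_rng(37)
        ds, inter, sim = random_fixture(rng, 12, 3)
        kf = kfold(ds, inter, sim, folds=12, repeats=1, seed=0)
        jk = jackknife(ds, inter, sim)
        assert kf.acc[0] == pytest.approx(jk.acc[0])

    def test_fold_sizes_near_equal(self):
        from indirank.evaluation import _partition
        rng = np.random.default_rng(0)
        parts = _partition(23, 5, rng)
        sizes = sorted(len(p) for p in parts)
        assert max(sizes) - min(sizes) <= 1
        assert sorted(np.concatenate(parts)) == list(range(23))

    def test_repeat_mean_close_to_jackknife_on_high_signal(self):
        from indirank.synthetic import SyntheticConfig, generate, \
            similarity_from_fingerprints
        ds, fps, inter, _ = generate(SyntheticConfig(n_drugs=100, seed=41,
                                                     bit_noise=0.02))
        sim = similarity_from_fingerprints(fps)
        jk = jackknife(ds, inter, sim)
        kf = kfold(ds, inter, sim, folds=5, repeats=5, seed=13)
        accs = [row[0] for row in kf.acc]
        spread = max(3 * np.std(accs, ddof=1), 0.03)
        assert abs(np.mean(accs) - jk.acc_mean[0]) <= spread

    def test_report_serializes(self):
        rng = np.random.default_rng(43)
        ds, inter, sim = random_fixture(rng, 15, 4)
        rep = kfold(ds, inter, sim, folds=3, repeats=2, seed=7)
        d = rep.to_dict()
        assert d["scheme"] == "kfold" and d["folds"] == 3
        assert len(d["acc"]["per_repeat"]) == 2
        assert d["acc"]["std"] is not None
        assert d["recall_t"]["mean"] == pytest.approx(np.mean(rep.recall_t))


class TestReportInvariants:
    def test_sum_of_order_hits_bounded_by_label_mass(self):
        """Each correct label occupies at most one rank, so the ACC vector
        sums to at most the average label count."""
        rng = np.random.default_rng(47)
        for _ in range(5):
            ds, inter, sim = random_fixture(rng, 15, 5)
            rep = jackknife(ds, inter, sim)
            for row in rep.acc:
                assert sum(row) <= rep.average_labels + 1e-9

    def test_random_ranking_null_matches_average_over_m(self):
        """A uniform random permutation of all tags scores ACC_1 near
        Average / m."""
        rng = np.random.default_rng(53)
        tags = [f"D_{i}" for i in range(1, 21)]
        truth = {f"d{j}": frozenset(rng.choice(tags,
                                               size=rng.choice([1, 2, 3], p=[0.77, 0.2, 0.03]),
                                               replace=False))
                 for j in range(2000)}
        preds = {}
        for d in truth:
            perm = rng.permutation(tags)
            scores = np.linspace(1.0, 0.1, len(tags))
            preds[d] = RankedPrediction(tuple(zip(perm, scores)))
        acc1 = order_accuracy(preds, truth, 1)
        avg, _ = average_labels(truth)
        expected = avg / len(tags)
        se = math.sqrt(expected * (1 - expected) / len(truth))
        assert abs(acc1 - expected) <= 4 * se
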
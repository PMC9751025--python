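import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from avcdiag.evaluate import (
    auc,
    auc_pair_count,
    bootstrap_ci,
    confusion,
    per_marker_auc,
    roc_summary,
    youden_threshold,
)
from avcdiag.fixtures import labels_from_sample_ids, load_fixture, table5_scores_and_labels
from avcdiag.io_preprocess import DISEASE, NORMAL, ExpressionMatrix, SampleSheet


def _labels(n_normal, n_disease):
    return np.array([NORMAL] * n_normal + [DISEASE] * n_disease)


def _random_instance(rng):
    n_n = int(rng.integers(2, 10))
    n_d = int(rng.integers(2, 10))
    # coarse grid forces plenty of exact ties
    scores = rng.integers(0, 5, size=n_n + n_d).astype(float)
    return scores, _labels(n_n, n_d)


class TestAuc:
    def test_perfect_separation_is_one(self):
        assert auc([0.1, 0.2, 0.8, 0.9], _labels(2, 2)) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc([1.0] * 6, _labels(3, 3)) == 0.5

    def test_rank_formula_equals_pair_count_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            scores, labels = _random_instance(rng)
            assert auc(scores, labels) == pytest.approx(
                auc_pair_count(scores, labels), abs=1e-12
            )

    def test_agrees_with_sklearn_on_tied_data(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            scores, labels = _random_instance(rng)
            ref = roc_auc_score((labels == DISEASE).astype(int), scores)
            assert auc(scores, labels) == pytest.approx(ref, abs=1e-12)

    def test_complement_identity(self):
        rng = np.random.default_rng(1)
        scores, labels = _random_instance(rng)
        assert auc(scores, labels) + auc(-np.asarray(scores), labels) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=10)
        labels = _labels(5, 5)
        assert auc(np.exp(scores), labels) == pytest.approx(auc(scores, labels))

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            auc([1.0, 2.0], np.array([NORMAL, NORMAL]))

    def test_worked_example_table5(self):
        scores, labels = table5_scores_and_labels()
        value = auc(scores, labels)
        assert value == pytest.approx(296 / 300)
        assert round(value, 3) == 0.987


class TestYoudenThreshold:
    def test_separable_returns_gap_midpoint(self):
        thr, sens, spec = youden_threshold([0.1, 0.2, 0.8, 0.9], _labels(2, 2))
        assert thr == pytest.approx(0.5)
        assert sens == 1.0 and spec == 1.0

    def test_tied_j_resolves_to_lower_threshold(self):
        # normals {0.1, 0.6}, disease {0.4, 0.9}: J=0.5 at 0.25 and 0.75
        thr, sens, spec = youden_threshold(
            [0.1, 0.6, 0.4, 0.9], _labels(2, 2)
        )
        assert thr == pytest.approx(0.25)
        assert sens == 1.0 and spec == 0.5

    def test_two_distinct_samples_fully_separated(self):
        thr, sens, spec = youden_threshold([0.3, 0.7], _labels(1, 1))
        assert sens == 1.0 and spec == 1.0


class TestBootstrapCi:
    def test_separated_classes_reach_upper_bound_one(self):
        scores = np.concatenate([np.zeros(10), np.ones(10)])
        lo, hi = bootstrap_ci(scores, _labels(10, 10), reps=200, seed=0)
        assert hi == 1.0

    def test_same_seed_reproduces_interval(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=12)
        labels = _labels(6, 6)
        assert bootstrap_ci(scores, labels, reps=100, seed=9) == bootstrap_ci(
            scores, labels, reps=100, seed=9
        )

    def test_table5_interval_brackets_auc(self):
        scores, labels = table5_scores_and_labels()
        lo, hi = bootstrap_ci(scores, labels, reps=500, seed=1)
        assert lo <= 296 / 300 <= hi
        assert hi == pytest.approx(1.0, abs=1e-9)


class TestConfusion:
    def test_worked_example_table6(self):
        t5 = load_fixture("table5")
        truth = labels_from_sample_ids(t5.index)
        predicted = np.where(
            t5["value_disease"].to_numpy() > t5["value_normal"].to_numpy(),
            DISEASE, NORMAL,
        )
        table = confusion(predicted, truth)
        assert table.loc["normal", "predicted_normal"] == 15
        assert table.loc["normal", "accuracy"] == 1.0
        assert table.loc["disease", "predicted_disease"] == 19
        assert table.loc["disease", "accuracy"] == pytest.approx(0.95)

    def test_identical_vectors_are_fully_accurate(self):
        labels = _labels(2, 3)
        table = confusion(labels, labels)
        assert (table["accuracy"] == 1.0).all()

    def test_single_error_rate(self):
        truth = np.array([NORMAL, NORMAL, NORMAL])
        pred = np.array([NORMAL, NORMAL, DISEASE])
        assert confusion(pred, truth).loc["normal", "accuracy"] == pytest.approx(2 / 3)

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError):
            confusion(np.array(["x"]), np.array([NORMAL]))


class TestPerMarkerAuc:
    def _setup(self, rows, genes):
        samples = [f"s{i}" for i in range(len(rows[0]))]
        m = ExpressionMatrix(pd.DataFrame(rows, index=genes, columns=samples))
        n = len(samples) // 2
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": samples,
            "group": [NORMAL] * n + [DISEASE] * (len(samples) - n),
            "batch": ["A"] * len(samples),
        }))
        return m, sheet

    def test_label_indicator_marker_scores_one(self):
        m, sheet = self._setup([[0, 0, 1, 1]], ["ind"])
        assert per_marker_auc(m, sheet, ["ind"]).loc["ind", "auc"] == 1.0

    def test_anticorrelated_marker_is_complement(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=8)
        m, sheet = self._setup([vals, -vals], ["up", "dn"])
        res = per_marker_auc(m, sheet, ["up", "dn"])
        assert res.loc["dn", "auc"] == pytest.approx(1 - res.loc["up", "auc"])
        assert not res.loc["dn", "oriented_up"] or res.loc["dn", "auc"] >= 0.5

    def test_strong_planted_marker_has_high_auc(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = np.concatenate([rng.normal(0, 0.5, 15), rng.normal(2, 0.5, 20)])
            m, sheet = self._setup([vals], ["mk"])
            sheet = SampleSheet(pd.DataFrame({
                "sample_id": m.sample_ids,
                "group": [NORMAL] * 15 + [DISEASE] * 20,
                "batch": ["A"] * 35,
            }))
            if per_marker_auc(m, sheet, ["mk"]).loc["mk", "auc"] > 0.9:
                hits += 1
        assert hits >= 19

    def test_missing_marker_raises(self):
        m, sheet = self._setup([[0, 1, 2, 3]], ["g"])
        with pytest.raises(KeyError):
            per_marker_auc(m, sheet, ["absent"])


class TestRocSummary:
    def test_invariants_hold_on_random_scores(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=20)
        labels = _labels(10, 10)
        res = roc_summary(scores, labels, reps=200, seed=0)
        assert res.ci_low <= res.auc <= res.ci_high
        assert 0.0 <= res.sensitivity <= 1.0
        assert 0.0 <= res.specificity <= 1.0
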
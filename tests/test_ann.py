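import numpy as np
import pandas as pd
import pytest

from avcdiag import ann
from avcdiag.ann import (
    AnnModel,
    diagnostic_values,
    extract_gene_weights,
    forward,
    linear_score,
    load_model,
    save_model,
    train,
)
from avcdiag.fixtures import labels_from_sample_ids, load_fixture
from avcdiag.genescore import GeneScoreTable
from avcdiag.io_preprocess import DISEASE, NORMAL


def _table(rows, markers):
    return GeneScoreTable(
        scores=pd.DataFrame(rows, columns=markers,
                            index=[f"s{i}" for i in range(len(rows))]),
        directions={m: "up" for m in markers},
    )


def _zero_model(p=2, h=3):
    return AnnModel(
        W1=np.zeros((p, h)), b1=np.zeros(h), W2=np.zeros((h, 2)), b2=np.zeros(2),
        markers=[f"m{i}" for i in range(p)],
    )


@pytest.fixture(scope="module")
def xor_like_toy():
    """Separable 4-pattern toy: label = first score bit."""
    t = _table([[0, 0], [0, 1], [1, 0], [1, 1]], ["a", "b"])
    labels = np.array([NORMAL, NORMAL, DISEASE, DISEASE])
    return t, labels


class TestForward:
    def test_zero_weights_give_half_half(self):
        model = _zero_model()
        out = forward(model, np.array([[1.0, 0.0], [0.3, -2.0]]))
        np.testing.assert_allclose(out, 0.5)

    def test_hand_computed_single_hidden_unit(self):
        model = AnnModel(
            W1=np.array([[1.0]]), b1=np.zeros(1),
            W2=np.array([[1.0, -1.0]]), b2=np.zeros(2),
            markers=["m"],
        )
        out = forward(model, np.array([[1.0]]))
        # softmax(1, -1)
        np.testing.assert_allclose(out[0], [0.8808, 0.1192], atol=1e-4)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        model = AnnModel(
            W1=rng.normal(size=(4, 5)), b1=rng.normal(size=5),
            W2=rng.normal(size=(5, 2)), b2=rng.normal(size=2),
            markers=list("abcd"),
        )
        out = forward(model, rng.integers(0, 2, size=(20, 4)).astype(float))
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_logit_shift_invariance(self):
        rng = np.random.default_rng(3)
        model = AnnModel(
            W1=rng.normal(size=(3, 4)), b1=rng.normal(size=4),
            W2=rng.normal(size=(4, 2)), b2=np.array([0.7, -0.2]),
            markers=list("xyz"),
        )
        shifted = AnnModel(
            W1=model.W1, b1=model.b1, W2=model.W2, b2=model.b2 + 11.0,
            markers=model.markers,
        )
        x = rng.integers(0, 2, size=(6, 3)).astype(float)
        np.testing.assert_allclose(forward(model, x), forward(shifted, x), atol=1e-9)

    def test_marker_count_mismatch_raises(self):
        with pytest.raises(ValueError, match="marker count"):
            forward(_zero_model(p=2), np.zeros((1, 3)))


class TestTrain:
    def test_separable_toy_fits_perfectly(self, xor_like_toy):
        t, labels = xor_like_toy
        model = train(t, labels, H=5, seed=0)
        assert model.meta["training_accuracy"] == 1.0
        assert model.meta["final_loss"] < 0.05

    def test_loss_trend_non_increasing_over_windows(self, xor_like_toy):
        t, labels = xor_like_toy
        model = train(t, labels, H=5, seed=1)
        hist = model.meta["history"]
        for i in range(0, len(hist) - 50):
            assert hist[i + 50] <= hist[i] + 1e-9

    def test_same_seed_is_bit_reproducible(self, xor_like_toy):
        t, labels = xor_like_toy
        m1 = train(t, labels, seed=3)
        m2 = train(t, labels, seed=3)
        np.testing.assert_array_equal(m1.W1, m2.W1)
        np.testing.assert_array_equal(m1.W2, m2.W2)
        assert m1.meta["steps"] == m2.meta["steps"]

    def test_single_class_raises(self, xor_like_toy):
        t, _ = xor_like_toy
        with pytest.raises(ValueError):
            train(t, np.array([NORMAL] * 4))

    def test_table3_reaches_duplicate_pattern_ceiling(self):
        """The all-zero pattern (8 normal, 1 disease) caps accuracy at 34/35
        and must be labelled normal."""
        t3 = load_fixture("table3")
        labels = labels_from_sample_ids(t3.sample_ids)
        model = train(t3, labels, seed=0)
        assert model.meta["training_accuracy"] == pytest.approx(34 / 35)
        diag = diagnostic_values(model, t3)
        assert diag.loc["GSM1246211_AVC", "predicted"] == NORMAL


class TestGeneWeights:
    def test_table4_maxima(self):
        t4 = load_fixture("table4")
        model = AnnModel(
            W1=t4["W1"], b1=np.zeros(5), W2=np.zeros((5, 2)), b2=np.zeros(2),
            markers=t4["markers"],
        )
        w = extract_gene_weights(model)
        assert w["GPM6A"] == pytest.approx(10.063427)
        assert w["CXCL16"] == pytest.approx(1.4422024)
        assert w["SCARA5"] == pytest.approx(9.616735)

    def test_single_hidden_unit_weight_is_itself(self):
        model = AnnModel(
            W1=np.array([[-0.25]]), b1=np.zeros(1), W2=np.zeros((1, 2)),
            b2=np.zeros(2), markers=["m"],
        )
        assert extract_gene_weights(model)["m"] == -0.25


class TestDiagnosticValues:
    def test_zero_model_gives_half_half(self):
        t = _table([[0, 1]], ["m0", "m1"])
        diag = diagnostic_values(_zero_model(), t)
        assert diag.iloc[0]["p_normal"] == pytest.approx(0.5)

    def test_duplicate_rows_get_identical_outputs(self):
        t = _table([[1, 0], [1, 0], [0, 1]], ["m0", "m1"])
        rng = np.random.default_rng(2)
        model = AnnModel(
            W1=rng.normal(size=(2, 3)), b1=rng.normal(size=3),
            W2=rng.normal(size=(3, 2)), b2=rng.normal(size=2),
            markers=["m0", "m1"],
        )
        diag = diagnostic_values(model, t)
        assert diag.iloc[0].equals(diag.iloc[1])

    def test_marker_mismatch_raises(self):
        t = _table([[0, 1]], ["x", "y"])
        with pytest.raises(ValueError, match="marker"):
            diagnostic_values(_zero_model(), t)


class TestLinearScore:
    def test_all_ones_row_sums_table4_gene_weights(self):
        t4 = load_fixture("table4")
        weights = pd.Series(t4["W1"].max(axis=1), index=t4["markers"])
        t = GeneScoreTable(
            scores=pd.DataFrame([[1] * 5], columns=t4["markers"], index=["s"]),
            directions={m: "up" for m in t4["markers"]},
        )
        assert linear_score(weights, t)["s"] == pytest.approx(31.7140064)

    def test_all_zero_row_scores_zero(self):
        w = pd.Series([1.0, 2.0], index=["a", "b"])
        t = _table([[0, 0]], ["a", "b"])
        assert linear_score(w, t).iloc[0] == 0.0

    def test_single_marker_returns_its_weight(self):
        w = pd.Series([3.5, 2.0], index=["a", "b"])
        t = _table([[1, 0]], ["a", "b"])
        assert linear_score(w, t).iloc[0] == 3.5


class TestModelIo:
    def test_round_trip_is_bit_exact(self, tmp_path, xor_like_toy):
        t, labels = xor_like_toy
        model = train(t, labels, seed=2)
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        save_model(model, p1)
        loaded = load_model(p1)
        save_model(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()
        np.testing.assert_array_equal(model.W1, loaded.W1)

    def test_missing_key_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"W1": [[0.0]], "W2": [[0.0, 0.0]], "b2": [0.0, 0.0], "markers": ["m"]}')
        with pytest.raises(ValueError, match="b1"):
            load_model(path)

    def test_table4_fixture_exposes_five_by_five_hidden_block(self):
        t4 = load_fixture("table4")
        assert t4["W1"].shape == (5, 5)
        assert t4["output_block"].shape == (5, 2)
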
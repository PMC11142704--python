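import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protmol.metrics import (
    MetricUndefinedError,
    binary_metrics,
    concordance_index,
    evaluate,
    regression_metrics,
    rm_squared,
)

from .oracles import auc_oracle, ci_oracle, mcc_oracle, regression_oracle, rm2_oracle


class TestRegressionMetrics:
    def test_perfect_fit(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["mse"] == 0.0 and m["r_squared"] == 1.0
        assert m["pearson_r"] == pytest.approx(1.0)

    def test_anti_fit_r_squared_negative(self):
        m = regression_metrics([0.0, 1.0], [1.0, 0.0])
        assert m["mse"] == pytest.approx(1.0)
        assert m["r_squared"] == pytest.approx(-3.0)

    def test_constant_prediction(self):
        y = [1.0, 2.0, 3.0]
        with pytest.raises(MetricUndefinedError):
            regression_metrics(y, [2.0, 2.0, 2.0])

    def test_zero_label_variance(self):
        with pytest.raises(MetricUndefinedError):
            regression_metrics([1.0, 1.0], [0.0, 1.0])


class TestConcordanceIndex:
    @pytest.mark.parametrize(
        "y, yhat, expected",
        [
            ([1, 2, 3], [0.1, 0.2, 0.3], 1.0),
            ([1, 2, 3], [0.1, 0.3, 0.2], 2 / 3),
            ([1, 1, 2], [0.5, 0.9, 0.9], 0.75),  # one label tie, one prediction tie
        ],
    )
    def test_worked_examples(self, y, yhat, expected):
        assert concordance_index(y, yhat) == pytest.approx(expected)

    def test_no_comparable_pairs(self):
        with pytest.raises(MetricUndefinedError):
            concordance_index([2.0, 2.0], [0.1, 0.2])

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_monotone_transform_invariance(self, data):
        n = data.draw(st.integers(3, 25))
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        y = rng.integers(0, 5, n).astype(float)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0.0, 1.0
        p = rng.normal(size=n)
        ci = concordance_index(y, p)
        assert concordance_index(y, np.exp(2 * p)) == pytest.approx(ci)


class TestRmSquared:
    def test_identity(self):
        out = rm_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["rm_squared"] == pytest.approx(1.0)
        assert out["r2"] == pytest.approx(1.0)
        assert out["r0_2"] == pytest.approx(1.0)

    def test_zero_intercept_fit_collapses(self):
        # predictions proportional to labels through the origin: the
        # with-intercept and through-origin fits coincide
        y = np.array([1.0, 2.0, 3.0, 4.0])
        out = rm_squared(y, 0.5 * y)
        assert out["r0_2"] == pytest.approx(out["r2"], abs=1e-12)
        assert out["rm_squared"] == pytest.approx(out["r2"], abs=1e-12)

    def test_against_oracle_example(self):
        y = [1.0, 2.0, 3.0, 4.0]
        yhat = [1.1, 1.9, 3.2, 3.8]
        expected, r2, r0_2 = rm2_oracle(y, yhat)
        out = rm_squared(y, yhat)
        assert out["rm_squared"] == pytest.approx(expected, rel=1e-12)
        assert out["r2"] == pytest.approx(r2, rel=1e-12)
        assert out["r0_2"] == pytest.approx(r0_2, rel=1e-12)

    def test_non_radical_variant(self):
        y = [1.0, 2.0, 3.0, 4.0]
        yhat = [1.4, 1.7, 3.6, 3.5]
        out_r = rm_squared(y, yhat, radical=True)
        out_n = rm_squared(y, yhat, radical=False)
        rad = out_r["r2"] - out_r["r0_2"]
        assert out_n["rm_squared"] == pytest.approx(out_r["r2"] * (1 - rad), rel=1e-12)

    def test_all_zero_predictions(self):
        with pytest.raises(MetricUndefinedError):
            rm_squared([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])


class TestBinaryMetrics:
    def test_perfect_separation(self):
        out = binary_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert out == {"accuracy": 1.0, "mcc": 1.0, "roc_auc": 1.0}

    def test_printed_confusion_table(self):
        # TP=3, TN=5, FP=1, FN=1 -> accuracy 0.8, MCC = 14/24
        y = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        p = [0.9, 0.8, 0.7, 0.2, 0.1, 0.1, 0.2, 0.3, 0.4, 0.6]
        out = binary_metrics(y, p)
        assert out["accuracy"] == pytest.approx(0.8)
        assert out["mcc"] == pytest.approx(14 / 24)

    def test_single_class_labels(self):
        with pytest.raises(MetricUndefinedError):
            binary_metrics([1, 1, 1], [0.2, 0.9, 0.7])

    def test_one_sided_predictions(self):
        with pytest.raises(MetricUndefinedError):
            binary_metrics([0, 1, 0], [0.9, 0.8, 0.7])

    @given(st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None)
    def test_class_swap_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        y = rng.integers(0, 2, n).astype(float)
        y[:2] = [0, 1]
        p = rng.uniform(0.0, 1.0, n)
        p = np.where(np.abs(p - 0.5) < 1e-6, 0.6, p)  # keep off the threshold
        try:
            m1 = binary_metrics(y, p)["mcc"]
            m2 = binary_metrics(1 - y, 1 - p + 1e-12)["mcc"]
        except MetricUndefinedError:
            return
        assert m2 == pytest.approx(m1, abs=1e-9)

    @given(st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None)
    def test_auc_equals_ci_on_binary_labels(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        y = rng.integers(0, 2, n).astype(float)
        y[:2] = [0, 1]
        p = rng.uniform(size=n)
        auc = binary_metrics(y, p)["roc_auc"]
        assert auc == pytest.approx(concordance_index(y, p), abs=1e-12)


def test_evaluate_regression_panel():
    rng = np.random.default_rng(3)
    y = rng.normal(size=40)
    p = y + rng.normal(scale=0.3, size=40)
    rep = evaluate(y, p, "regression").to_dict()
    assert set(rep) == {
        "mse", "r_squared", "pearson_r", "concordance_index",
        "rm_squared", "rm_r2", "rm_r0_2",
    }
    assert rep["concordance_index"] == pytest.approx(ci_oracle(y, p))


def test_oracle_agreement_randomised():
    """Implementations match brute-force oracles on random vectors."""
    rng = np.random.default_rng(42)
    for _ in range(30):
        n = int(rng.integers(3, 80))
        y = rng.normal(size=n)
        p = y * rng.uniform(-1, 1.5) + rng.normal(scale=rng.uniform(0.1, 2), size=n)
        mse, r2, pe = regression_oracle(y, p)
        m = regression_metrics(y, p)
        assert m["mse"] == pytest.approx(mse, rel=1e-10)
        assert m["r_squared"] == pytest.approx(r2, rel=1e-10)
        assert m["pearson_r"] == pytest.approx(pe, rel=1e-10)
        assert concordance_index(y, p) == pytest.approx(ci_oracle(y, p), rel=1e-12)
        assert rm_squared(y, p)["rm_squared"] == pytest.approx(rm2_oracle(y, p)[0], rel=1e-9)

        yb = rng.integers(0, 2, n).astype(float)
        yb[: 2] = [0, 1]
        pb = rng.uniform(size=n)
        try:
            out = binary_metrics(yb, pb)
        except MetricUndefinedError:
            continue  # one-sided thresholded predictions at small n
        assert out["roc_auc"] == pytest.approx(auc_oracle(yb, pb), rel=1e-12)
        assert out["mcc"] == pytest.approx(mcc_oracle(yb, pb), rel=1e-10)
        assert out["accuracy"] == pytest.approx(np.mean((pb >= 0.5) == yb), rel=1e-12)
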
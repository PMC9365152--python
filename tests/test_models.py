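"""Adjusted R², forest fitting, and the paired MCCV comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regmut.models import (
    ModelSpec,
    adjusted_r2,
    downsample_arms,
    fit_forest,
    mccv_compare,
)

SPEC = ModelSpec(n_trees=50, n_splits=20, seed=7)


def _adj_r2_oracle(obs, pred, p):
    """Brute-force restatement of the formula, kept independent."""
    obs, pred = np.asarray(obs, float), np.asarray(pred, float)
    n = len(obs)
    r2 = 1 - np.sum((obs - pred) ** 2) / np.sum((obs - np.mean(obs)) ** 2)
    return 1 - (1 - r2) * (n - 1) / (n - p - 1)


class TestAdjustedR2:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 5.0])
        assert adjusted_r2(y, y, 1) == pytest.approx(1.0)

    def test_mean_prediction_zero_at_p0(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert adjusted_r2(y, np.full(4, y.mean()), 0) == pytest.approx(0.0)

    def test_worked_example(self):
        y = np.array([1, 2, 3, 4.0])
        pred = np.array([1.1, 1.9, 3.2, 3.8])
        r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 == pytest.approx(0.98)
        assert adjusted_r2(y, pred, 1) == pytest.approx(0.97)

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError, match="adjustment undefined"):
            adjusted_r2(np.arange(3.0), np.arange(3.0), 2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            adjusted_r2(np.ones(5), np.ones(5), 1)

    @given(
        n=st.integers(min_value=8, max_value=60),
        p=st.integers(min_value=0, max_value=5),
        s=st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle(self, n, p, s):
        r = np.random.default_rng(s)
        y = r.normal(size=n)
        pred = y + r.normal(scale=0.5, size=n)
        assert adjusted_r2(y, pred, p) == pytest.approx(
            _adj_r2_oracle(y, pred, p), abs=1e-12
        )

    def test_equals_plain_r2_at_p0(self, rng):
        y = rng.normal(size=30)
        pred = y + rng.normal(scale=0.3, size=30)
        r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert adjusted_r2(y, pred, 0) == pytest.approx(r2)


class TestFitForest:
    def test_noiseless_monotone_signal_recovered(self):
        from regmut.models import mccv_adj_r2

        r = np.random.default_rng(7)
        x = r.normal(size=(500, 2))
        y = np.tanh(1.5 * x[:, 0])  # bounded monotone: no heavy-tail splits
        r2 = mccv_adj_r2(x, y, ModelSpec(n_trees=100, n_splits=5, seed=1))
        assert np.median(r2) > 0.95

    def test_independent_response_near_zero(self, rng):
        x = rng.normal(size=(300, 3))
        y = rng.normal(size=300)
        fit = fit_forest(x, y, SPEC)
        assert fit.oob_adj_r2 < 0.15

    def test_deterministic_under_seed(self, rng):
        x = rng.normal(size=(100, 3))
        y = x[:, 0] + rng.normal(size=100)
        a = fit_forest(x, y, SPEC)
        b = fit_forest(x, y, SPEC)
        np.testing.assert_array_equal(a.oob_prediction, b.oob_prediction)

    def test_degenerate_response_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate response"):
            fit_forest(rng.normal(size=(50, 2)), np.ones(50), SPEC)

    def test_residuals_are_observed_minus_oob(self, rng):
        x = rng.normal(size=(80, 2))
        y = x[:, 0] + rng.normal(size=80)
        fit = fit_forest(x, y, SPEC)
        np.testing.assert_allclose(fit.residuals, y - fit.oob_prediction)


class TestMccvCompare:
    @pytest.fixture(scope="class")
    def xy(self):
        r = np.random.default_rng(11)
        latent = r.normal(size=200)
        cancer = pd.DataFrame(
            {f"c{i}": latent + r.normal(scale=0.4, size=200) for i in range(3)}
        )
        normal = pd.DataFrame(
            {f"n{i}": r.normal(size=200) for i in range(3)}  # uninformative
        )
        y = np.exp(1.0 + 0.8 * latent) + r.normal(scale=0.5, size=200)
        return cancer, normal, y

    def test_identical_arms_symmetric(self, xy):
        cancer, _, y = xy
        res = mccv_compare(cancer, cancer, None, y, SPEC)
        assert res.median_delta == 0.0
        assert res.empirical_p == pytest.approx(0.5)

    def test_informative_cancer_arm_wins(self, xy):
        cancer, normal, y = xy
        res = mccv_compare(cancer, normal, None, y, ModelSpec(n_trees=50, n_splits=40, seed=3))
        assert res.median_delta > 0
        assert res.empirical_p < 0.05
        assert res.ci_low <= res.median_delta <= res.ci_high

    def test_swap_negates_deltas_exactly(self, xy):
        cancer, normal, y = xy
        a = mccv_compare(cancer, normal, None, y, SPEC)
        b = mccv_compare(normal, cancer, None, y, SPEC)
        np.testing.assert_allclose(a.deltas, -b.deltas)
        assert a.empirical_p == b.empirical_p

    def test_all_positive_reports_below_floor(self, xy):
        cancer, normal, y = xy
        res = mccv_compare(cancer, normal, None, y, ModelSpec(n_trees=50, n_splits=40, seed=3))
        assert np.all(res.deltas > 0)  # planted contrast is unambiguous
        assert res.p_label.startswith("<")
        assert res.empirical_p == pytest.approx(1 / 40)

    def test_too_few_test_windows_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(20, 2)))
        y = rng.normal(size=20)
        with pytest.raises(ValueError, match="fewer than 10 test windows"):
            mccv_compare(x, x, None, y, ModelSpec(n_trees=10, n_splits=2, seed=0))


class TestDownsampleArms:
    def test_larger_arm_subsampled(self):
        subsets = downsample_arms([f"c{i}" for i in range(10)], ["n1", "n2", "n3", "n4"], n_iter=5, seed=1)
        for c, n in subsets:
            assert len(c) == 4 and len(n) == 4
            assert n == ["n1", "n2", "n3", "n4"]

    def test_equal_sizes_identity(self):
        subsets = downsample_arms(["a", "b"], ["x", "y"], n_iter=3, seed=1)
        assert all(c == ["a", "b"] and n == ["x", "y"] for c, n in subsets)

    def test_seed_reproducible(self):
        a = downsample_arms(list("abcdefgh"), list("xy"), n_iter=4, seed=9)
        b = downsample_arms(list("abcdefgh"), list("xy"), n_iter=4, seed=9)
        assert a == b


def test_oob_residuals_nearly_unbiased_on_synthetic_burden():
    """Mean OOB residual stays below 2% of mean burden, averaged over
    generator replicates."""
    from regmut.burden import PAN_CANCER, count_burden
    from regmut.synthdata import default_scenario

    biases = []
    for rep in range(3):
        scen = default_scenario(seed=8000 + rep)
        y = count_burden(scen["snvs"], scen["grid"], PAN_CANCER).counts
        fit = fit_forest(scen["X"], y, ModelSpec(n_trees=100, seed=rep))
        biases.append(abs(fit.residuals.mean()) / y.mean())
    assert np.mean(biases) < 0.02, f"relative biases {np.round(biases, 4)}"
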
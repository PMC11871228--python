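"""Regression selection, rank tests and redundancy analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plumemix.stats import (
    kruskal_wallis,
    levene,
    rda,
    select_regression,
    shapiro_wilk,
    spearman,
)


class TestSelectRegression:
    def test_noiseless_linear_selects_linear(self):
        x = np.linspace(0, 5, 20)
        fit = select_regression(x, 2 * x + 1)
        assert fit.model == "linear"
        assert fit.rmse == pytest.approx(0, abs=1e-9)
        assert fit.slope == pytest.approx(2.0)

    def test_pure_quadratic_selects_quadratic(self):
        x = np.linspace(-1, 1, 21)
        fit = select_regression(x, x**2)
        assert fit.model == "quadratic"
        assert fit.rmse == pytest.approx(0, abs=1e-9)
        # the linear candidate has ~zero slope and positive RMSE
        assert fit.linear.rmse > 0.1
        assert abs(fit.linear.coefficients[1]) < 1e-9

    def test_both_candidates_retained(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 1, 30)
        fit = select_regression(x, 3 * x + rng.normal(0, 0.1, 30))
        assert fit.linear is not None and fit.quadratic is not None
        assert fit.quadratic.degree == 2

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            select_regression(np.ones(10), np.arange(10.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            select_regression([1, 2, 3], [1, 2, 3])

    def test_never_worse_on_both_criteria(self):
        # the selected model is never inferior on p AND RMSE simultaneously
        rng = np.random.default_rng(42)
        for _ in range(30):
            x = rng.uniform(0, 1, 25)
            y = rng.normal(0, 1, 25) + rng.uniform(-2, 2) * x + rng.uniform(-2, 2) * x**2
            fit = select_regression(x, y)
            sel, other = (fit.linear, fit.quadratic) if fit.model == "linear" else (fit.quadratic, fit.linear)
            worse_p = sel.p_value > other.p_value * (1 + 1e-9)
            worse_rmse = sel.rmse > other.rmse * (1 + 1e-9)
            assert not (worse_p and worse_rmse)

    def test_ci_band_contains_fitted_curve(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 1, 40)
        y = 1 + 2 * x + rng.normal(0, 0.2, 40)
        fit = select_regression(x, y)
        yhat = np.polyval(fit.coefficients[::-1], fit.x_sorted)
        assert np.all(fit.ci95_lower <= yhat + 1e-9)
        assert np.all(yhat <= fit.ci95_upper + 1e-9)


class TestSpearman:
    def test_monotone_is_one(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)

    def test_antitone_is_minus_one(self):
        x = np.arange(10.0)
        assert spearman(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)

    def test_zero_variance_missing(self):
        rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho)

    @given(st.integers(0, 1000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r1, _ = spearman(x, y)
        r2, _ = spearman(np.exp(x), y**3)
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        r = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert r.statistic == pytest.approx(0, abs=1e-9)

    def test_hand_computed_h(self):
        # no-ties rank-sum arithmetic: H = 12/(6*7)*(9/2+49/2+121/2) - 21
        r = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert r.statistic == pytest.approx(4.5714, abs=1e-3)

    def test_scale_invariance(self):
        g = [[1.0, 2, 7], [3.0, 4, 1], [5.0, 6, 2]]
        r1 = kruskal_wallis(g)
        r2 = kruskal_wallis([[10 * v for v in grp] for grp in g])
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_all_constant_p_one(self):
        r = kruskal_wallis([[5, 5], [5, 5]])
        assert r.statistic == 0 and r.p_value == 1

    def test_undersized_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1]])


class TestVarianceAndNormality:
    def test_equal_spread_levene_large_p(self):
        rng = np.random.default_rng(10)
        r = levene([rng.normal(0, 1, 50), rng.normal(0, 1, 50)])
        assert r.p_value > 0.5

    def test_unequal_spread_levene_small_p(self):
        rng = np.random.default_rng(10)
        r = levene([rng.normal(0, 1, 50), rng.normal(0, 10, 50)])
        assert r.p_value < 0.01

    def test_uniform_sample_fails_shapiro(self):
        rng = np.random.default_rng(3)
        r = shapiro_wilk(rng.uniform(0, 1, 500))
        assert r.p_value < 0.01

    def test_normal_sample_passes_shapiro(self):
        rng = np.random.default_rng(3)
        r = shapiro_wilk(rng.normal(0, 1, 200))
        assert r.p_value > 0.05

    def test_undersized_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            levene([[1.0], [2.0, 3.0]])


class TestRDA:
    def test_perfect_fit_fraction_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        Y = pd.DataFrame({"y1": X["a"] + X["b"], "y2": 2 * X["a"] - X["b"]})
        r = rda(Y, X)
        assert r.constrained_fraction == pytest.approx(1.0, abs=1e-9)

    def test_matches_external_ordination_oracle(self):
        # expected values computed once with an independent constrained-
        # ordination implementation (vegan::rda on the same matrices)
        rng = np.random.default_rng(42)
        n = 15
        X = rng.standard_normal((n, 2))
        B = np.array([[1.0, -0.5, 0.3], [0.2, 0.8, -0.4]])
        Y = X @ B + 0.5 * rng.standard_normal((n, 3))
        r = rda(pd.DataFrame(Y, columns=list("abc")), pd.DataFrame(X, columns=["x1", "x2"]))
        assert r.constrained_fraction == pytest.approx(0.690617, abs=1e-5)
        np.testing.assert_allclose(r.axis_fractions, [0.3963943, 0.2942227], atol=1e-5)

    def test_pure_noise_fraction_near_p_over_n(self):
        rng = np.random.default_rng(5)
        fracs = []
        for _ in range(20):
            Y = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
            X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("wxyz"))
            fracs.append(rda(Y, X).constrained_fraction)
        assert np.mean(fracs) == pytest.approx(4 / 199, abs=0.01)

    def test_duplicated_column_dropped_same_result(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(25, 2)), columns=["a", "b"])
        Y = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("uvw"))
        base = rda(Y, X)
        X2 = X.copy()
        X2["a_dup"] = X["a"]
        dup = rda(Y, X2)
        assert dup.dropped_columns == ("a_dup",)
        assert dup.constrained_fraction == pytest.approx(base.constrained_fraction, abs=1e-9)

    def test_contribution_ranking_identifies_driver(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=["driver", "weak", "noise"])
        Y = pd.DataFrame({
            "y1": 3 * X["driver"] + 0.2 * X["weak"] + rng.normal(0, 0.3, 60),
            "y2": -2 * X["driver"] + rng.normal(0, 0.3, 60),
        })
        r = rda(Y, X)
        assert r.contributions.index[0] == "driver"
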
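"""Statistical stage: regression selection, rank tests and RDA.

The fraction–response relationships (e.g. brassicasterol share vs KSSW
fraction) are fitted with both a straight line and a quadratic; the
linear model is kept when both its overall-F p value and its RMSE are
lower, otherwise the quadratic.  Group comparisons between subregions
use the Kruskal–Wallis rank-sum test, preceded by Shapiro–Wilk normality
and Brown–Forsythe (median-centred Levene) variance-homogeneity checks
that justify the rank-based choice.  Redundancy analysis (RDA)
summarizes how much biomarker variance the hydrographic variables
explain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA = 0.05  # significance level used throughout the pipeline

# near-equality tolerance when comparing the two candidate fits; exact
# fits give both models ~1e-16 RMSE and the comparison must not hinge
# on floating-point noise
_EQ_RTOL = 1e-8
_EQ_ATOL = 1e-10


@dataclass
class FitCandidate:
    degree: int
    coefficients: np.ndarray      # intercept first
    r2: float
    rmse: float
    p_value: float                # overall F


@dataclass
class ModelFit:
    """Selected model with both candidates retained for the report."""

    model: str                    # 'linear' or 'quadratic'
    coefficients: np.ndarray
    r2: float
    rmse: float
    p_value: float
    ci95_lower: np.ndarray        # pointwise band at the sorted x values
    ci95_upper: np.ndarray
    x_sorted: np.ndarray
    linear: FitCandidate | None = None
    quadratic: FitCandidate | None = None
    selection_conflict: bool = False

    @property
    def slope(self) -> float:
        return float(self.coefficients[1])

    def slope_ci95(self) -> tuple[float, float]:
        """95% CI of the first-order coefficient of the selected model."""
        return self._slope_ci

    _slope_ci: tuple[float, float] = (np.nan, np.nan)


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    test_name: str
    group_ns: tuple[int, ...]


def _fit_poly(x: np.ndarray, y: np.ndarray, degree: int):
    X = np.column_stack([x**d for d in range(degree + 1)])
    res = sm.OLS(y, X).fit()
    # degrees-of-freedom-adjusted root-MSE (the residual standard error
    # regression software prints); without the adjustment the quadratic,
    # which nests the line, could never lose on RMSE
    dof = max(x.size - (degree + 1), 1)
    rmse = float(np.sqrt(np.sum(res.resid**2) / dof))
    p = float(res.f_pvalue)
    if not np.isfinite(p):  # e.g. perfect fit
        p = 0.0 if res.rsquared > 1 - 1e-12 else 1.0
    cand = FitCandidate(degree, np.asarray(res.params), float(res.rsquared), rmse, p)
    return cand, res


def _lower(a: float, b: float) -> bool:
    """a strictly lower than b beyond floating-point noise."""
    return a < b and not np.isclose(a, b, rtol=_EQ_RTOL, atol=_EQ_ATOL)


def select_regression(x, y) -> ModelFit:
    """Fit degree-1 and degree-2 least squares and pick one.

    The quadratic replaces the line only when it is better on both the
    overall-F p value and the df-adjusted RMSE; when the two criteria
    disagree the simpler model is kept (parsimony) and the conflict is
    logged and flagged.  Near-equality at floating-point precision also
    counts for the line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: x is constant")

    lin, lin_res = _fit_poly(x, y, 1)
    quad, quad_res = _fit_poly(x, y, 2)

    p_favors_lin = not _lower(quad.p_value, lin.p_value)
    rmse_favors_lin = not _lower(quad.rmse, lin.rmse)
    conflict = p_favors_lin != rmse_favors_lin
    use_linear = p_favors_lin or rmse_favors_lin
    if conflict:
        logger.info(
            "model-selection conflict (p: %s, rmse: %s); keeping the simpler model",
            "linear" if p_favors_lin else "quadratic",
            "linear" if rmse_favors_lin else "quadratic",
        )

    chosen, res = (lin, lin_res) if use_linear else (quad, quad_res)
    order = np.argsort(x)
    Xs = np.column_stack([x[order] ** d for d in range(chosen.degree + 1)])
    band = res.get_prediction(Xs).conf_int(alpha=ALPHA)
    ci = res.conf_int(alpha=ALPHA)
    fit = ModelFit(
        model="linear" if use_linear else "quadratic",
        coefficients=chosen.coefficients,
        r2=chosen.r2,
        rmse=chosen.rmse,
        p_value=chosen.p_value,
        ci95_lower=band[:, 0],
        ci95_upper=band[:, 1],
        x_sorted=x[order],
        linear=lin,
        quadratic=quad,
        selection_conflict=conflict,
    )
    fit._slope_ci = (float(ci[1, 0]), float(ci[1, 1]))
    return fit


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("Spearman undefined: zero variance in ranks")
        return np.nan, np.nan
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def kruskal_wallis(groups) -> GroupTestResult:
    """Kruskal–Wallis H (tie-corrected) with chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups) or sum(g.size for g in groups) < 3:
        raise ValueError("need >= 2 groups, total n >= 3")
    ns = tuple(g.size for g in groups)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return GroupTestResult(0.0, 1.0, "kruskal-wallis", ns)
    h, p = sps.kruskal(*groups)
    return GroupTestResult(float(h), float(p), "kruskal-wallis", ns)


def levene(groups) -> GroupTestResult:
    """Brown–Forsythe test (ANOVA on |x - group median|) for equal spread."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    stat, p = sps.levene(*groups, center="median")
    return GroupTestResult(float(stat), float(p), "levene (brown-forsythe)", tuple(g.size for g in groups))


def shapiro_wilk(x) -> GroupTestResult:
    """Shapiro–Wilk normality test, valid for 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    w, p = sps.shapiro(x)
    return GroupTestResult(float(w), float(p), "shapiro-wilk", (x.size,))


# ---------------------------------------------------------------------------
# redundancy analysis

@dataclass
class RDAResult:
    """Constrained-ordination summary.

    ``axis_fractions`` are the shares of total (standardized) response
    variance carried by each constrained axis; their sum is
    ``constrained_fraction``. ``contributions`` holds, per explanatory
    variable, the marginal constrained fraction obtained by that
    variable alone — used only to rank the variables, not additive under
    collinearity.
    """

    constrained_fraction: float
    axis_fractions: np.ndarray
    variable_scores: pd.DataFrame      # explanatory x axis correlations
    contributions: pd.Series           # per explanatory variable, ranked desc
    dropped_columns: tuple[str, ...]
    n_used: int


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    keep = sd[sd > 0].index
    dropped = [c for c in df.columns if c not in set(keep)]
    if dropped:
        logger.warning("dropping zero-variance columns: %s", dropped)
    z = (df[keep] - df[keep].mean()) / df[keep].std(ddof=1)
    return z


def rda(response: pd.DataFrame, explanatory: pd.DataFrame) -> RDAResult:
    """Redundancy analysis of biomarker responses on hydrographic predictors.

    Rows with any missing value are dropped (and logged); both matrices
    are standardized to zero mean / unit variance.  The fitted values of
    the multivariate regression of Y on X are eigen-decomposed; mutually
    collinear X columns are removed left-to-right with a warning.
    """
    joined = pd.concat([response, explanatory], axis=1)
    mask = joined.notna().all(axis=1)
    if (~mask).any():
        logger.warning("RDA: dropping %d rows with missing values", int((~mask).sum()))
    Y = _standardize(response[mask])
    X = _standardize(explanatory[mask])
    n = len(Y)
    if n <= X.shape[1] + 1:
        raise ValueError("too few complete rows for the number of predictors")

    # greedy collinearity filter: keep columns that increase rank
    kept_cols: list[str] = []
    dropped: list[str] = []
    for c in X.columns:
        trial = X[kept_cols + [c]].to_numpy()
        if np.linalg.matrix_rank(trial, tol=1e-8 * n) > len(kept_cols):
            kept_cols.append(c)
        else:
            dropped.append(c)
    if dropped:
        logger.warning("RDA: dropping collinear predictors %s", dropped)
    Xm = X[kept_cols].to_numpy()
    Ym = Y.to_numpy()

    beta, *_ = np.linalg.lstsq(Xm, Ym, rcond=None)
    Yhat = Xm @ beta
    total = float(np.sum(Ym**2))
    constrained = float(np.sum(Yhat**2)) / total

    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    k = min(len(kept_cols), Ym.shape[1])
    axis_fractions = (s[:k] ** 2) / total
    site_scores = U[:, :k] * s[:k]

    # structure coefficients: correlation of each predictor with each axis
    scores = {}
    for j, c in enumerate(kept_cols):
        scores[c] = [
            float(np.corrcoef(Xm[:, j], site_scores[:, a])[0, 1]) if s[a] > 1e-12 else 0.0
            for a in range(k)
        ]
    variable_scores = pd.DataFrame(scores, index=[f"RDA{a + 1}" for a in range(k)]).T

    contrib = {}
    for j, c in enumerate(kept_cols):
        xj = Xm[:, [j]]
        bj, *_ = np.linalg.lstsq(xj, Ym, rcond=None)
        contrib[c] = float(np.sum((xj @ bj) ** 2)) / total
    contributions = pd.Series(contrib).sort_values(ascending=False)

    return RDAResult(
        constrained_fraction=constrained,
        axis_fractions=axis_fractions,
        variable_scores=variable_scores,
        contributions=contributions,
        dropped_columns=tuple(dropped),
        n_used=n,
    )
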
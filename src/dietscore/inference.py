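"""Metric-validation statistics.

Everything needed to validate one diet metric against another on the same
sample: Spearman correlations with Fisher-z confidence intervals, a test for
comparing two *dependent* (overlapping) correlations sharing the outcome
variable, quintile assignment with optional person weights, quintile
logistic odds ratios with covariate adjustment and a 0–4-coded linear trend
test, a cross-metric Wald test on the two fifth-quintile coefficients in a
joint model, and the linear-regression analogue for a continuous outcome.

Survey design is simplified to optional person weights (fitted as variance
weights); that simplification is recorded in each result's metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import CollinearityError, ConvergenceError, DegenerateInputError

DESIGN_NOTE = "complex survey design simplified to optional person weights"


# ---------------------------------------------------------------------------
# correlations

@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    n: int


def _check_not_constant(*arrays):
    for a in arrays:
        if np.ptp(np.asarray(a, dtype=float)) == 0:
            raise DegenerateInputError("constant input: correlation undefined")


def spearman_ci(x, y, *, alpha: float = 0.05) -> CorrelationResult:
    """Spearman rank correlation with a Fisher-z confidence interval.

    Ties receive average ranks.  The interval uses the rank-correlation
    variance 1.06 / (n - 3) on the z scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("paired inputs of length >= 4 required")
    _check_not_constant(x, y)
    rho = float(stats.spearmanr(x, y).statistic)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    se = np.sqrt(1.06 / (len(x) - 3))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return CorrelationResult(
        rho=rho,
        ci_low=float(np.tanh(z - zcrit * se)),
        ci_high=float(np.tanh(z + zcrit * se)),
        n=len(x),
    )


@dataclass(frozen=True)
class DependentCorrelationTest:
    statistic: float
    p: float
    rho1: float
    rho2: float
    method: str  # 'analytic (Meng-Rosenthal-Rubin z on ranks)' or 'permutation'


def _spearman(x, y) -> float:
    return float(stats.spearmanr(x, y).statistic)


def compare_dependent_correlations(
    x1,
    x2,
    y,
    *,
    method: str = "analytic",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> DependentCorrelationTest:
    """Test H0: cor(x1, y) = cor(x2, y) for two metrics on the same subjects.

    Analytic mode: the Meng–Rosenthal–Rubin z test for overlapping dependent
    correlations, applied to Fisher-transformed Spearman coefficients (the
    correlation among the two predictors enters the variance).  Permutation
    mode: the x1/x2 labels are swapped independently within subject and the
    observed difference of coefficients is referred to the swap distribution.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not (len(x1) == len(x2) == n) or n < 4:
        raise ValueError("x1, x2, y must be equal-length with n >= 4")
    _check_not_constant(x1, x2, y)

    r1 = _spearman(x1, y)
    r2 = _spearman(x2, y)

    if method == "analytic":
        r12 = _spearman(x1, x2)
        if r12 >= 1.0 - 1e-12:
            # identical metrics: nothing to compare
            return DependentCorrelationTest(0.0, 1.0, r1, r2,
                                            "analytic (Meng-Rosenthal-Rubin z on ranks)")
        z1, z2 = np.arctanh(r1), np.arctanh(r2)
        rbar2 = (r1**2 + r2**2) / 2.0
        f = min((1.0 - r12) / (2.0 * (1.0 - rbar2)), 1.0)
        h = (1.0 - f * rbar2) / (1.0 - rbar2)
        zstat = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - r12) * h))
        p = 2.0 * stats.norm.sf(abs(zstat))
        return DependentCorrelationTest(float(zstat), float(p), r1, r2,
                                        "analytic (Meng-Rosenthal-Rubin z on ranks)")

    if method == "permutation":
        rng = np.random.default_rng(seed)
        obs = abs(r1 - r2)
        hits = 0
        for _ in range(n_perm):
            swap = rng.random(n) < 0.5
            a = np.where(swap, x2, x1)
            b = np.where(swap, x1, x2)
            if abs(_spearman(a, y) - _spearman(b, y)) >= obs - 1e-15:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        return DependentCorrelationTest(float(r1 - r2), float(p), r1, r2, "permutation")

    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# quintiles

def _weighted_quantile(values, weights, probs):
    """Inverse of the weighted ECDF: smallest value with F(v) >= p."""
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    cw = np.cumsum(weights[order])
    cw = cw / cw[-1]
    return np.array([v[np.searchsorted(cw, p, side="left")] for p in probs])


def assign_quintiles(values, weights=None) -> np.ndarray:
    """Quintile labels 1..5 cut at the (weighted) 20/40/60/80th percentiles.

    Values exactly equal to a boundary all receive the lower quintile
    (cumulative-distribution cutting).  With too few distinct values to form
    five groups a warning is issued and the degenerate labelling returned.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 5:
        raise ValueError("need at least 5 observations to form quintiles")
    probs = (0.2, 0.4, 0.6, 0.8)
    if weights is None:
        cuts = np.percentile(values, [100 * p for p in probs])
    else:
        weights = np.asarray(weights, dtype=float)
        if (weights < 0).any() or weights.sum() <= 0:
            raise ValueError("weights must be non-negative with positive total")
        cuts = _weighted_quantile(values, weights, probs)
    if len(np.unique(cuts)) < 4:
        warnings.warn(
            "fewer than 5 distinct quintile boundaries: degenerate labelling",
            stacklevel=2,
        )
    return (np.searchsorted(np.sort(cuts), values, side="left") + 1).astype(int)


# ---------------------------------------------------------------------------
# model design helpers

def _covariate_matrix(covariates, n) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame(index=pd.RangeIndex(n))
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    if len(cov) != n:
        raise ValueError("covariate rows do not match outcome length")
    cat = cov.select_dtypes(include=["object", "category", "bool"]).columns
    out = pd.get_dummies(cov, columns=list(cat), drop_first=True, dtype=float)
    return out.astype(float)


def _quintile_dummies(quintiles, prefix) -> pd.DataFrame:
    q = np.asarray(quintiles, dtype=int)
    if not np.isin(q, [1, 2, 3, 4, 5]).all():
        raise ValueError("quintile labels must be integers 1..5")
    # a level can be empty under heavy ties (degenerate cutting); its dummy
    # is omitted rather than entering the design as an all-zero column
    present = set(np.unique(q))
    return pd.DataFrame(
        {f"{prefix}q{j}": (q == j).astype(float) for j in (2, 3, 4, 5) if j in present}
    )


def _check_rank(X: pd.DataFrame):
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise CollinearityError(
            f"design matrix is rank deficient (columns: {list(X.columns)})"
        )


def _fit_logistic(y, X: pd.DataFrame, weights=None):
    _check_rank(X)
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    kwargs = {}
    if weights is not None:
        kwargs["var_weights"] = np.asarray(weights, dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            model = sm.GLM(np.asarray(y, dtype=float), X, family=sm.families.Binomial(), **kwargs)
            fit = model.fit(maxiter=200)
    except (PerfectSeparationError, RuntimeWarning) as e:
        raise ConvergenceError(f"logistic fit failed (separation?): {e}") from e
    if np.abs(fit.params).max() > 30:
        raise ConvergenceError(
            "logistic fit diverged: a coefficient exceeds 30 on the log-odds "
            "scale, which indicates (quasi-)separation"
        )
    return fit


# ---------------------------------------------------------------------------
# quintile models

@dataclass(frozen=True)
class QuintileModelResult:
    or_by_quintile: dict  # {1: (1.0, nan, nan), 2: (or, lo, hi), ...}
    p_trend: float
    trend_slope: float
    trend_slope_ci: tuple
    params: pd.Series
    cov_params: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def quintile_logistic(
    outcome,
    quintiles,
    covariates=None,
    weights=None,
    *,
    alpha: float = 0.05,
) -> QuintileModelResult:
    """Odds ratios for a binary outcome across metric quintiles (Q1 reference).

    Maximum-likelihood logistic fit of the outcome on quintile indicator
    variables plus covariates; ORs are exponentiated coefficients with Wald
    CIs.  The trend p-value comes from a refit with the quintile entered as
    the numeric code 0 (Q1) .. 4 (Q5).
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateInputError("outcome has a single class")
    n = len(y)
    dummies = _quintile_dummies(quintiles, "")
    X = pd.concat([dummies, _covariate_matrix(covariates, n)], axis=1)
    X.insert(0, "const", 1.0)
    fit = _fit_logistic(y, X, weights)

    zcrit = stats.norm.ppf(1 - alpha / 2)
    ors = {1: (1.0, np.nan, np.nan)}
    for j in (2, 3, 4, 5):
        if f"q{j}" not in fit.params:
            ors[j] = (np.nan, np.nan, np.nan)  # empty quintile level
            continue
        b = fit.params[f"q{j}"]
        se = fit.bse[f"q{j}"]
        ors[j] = (float(np.exp(b)), float(np.exp(b - zcrit * se)), float(np.exp(b + zcrit * se)))

    code = (np.asarray(quintiles, dtype=int) - 1).astype(float)
    Xt = pd.concat(
        [pd.DataFrame({"trend": code}), _covariate_matrix(covariates, n)], axis=1
    )
    Xt.insert(0, "const", 1.0)
    tfit = _fit_logistic(y, Xt, weights)
    slope = float(tfit.params["trend"])
    se = float(tfit.bse["trend"])

    return QuintileModelResult(
        or_by_quintile=ors,
        p_trend=float(tfit.pvalues["trend"]),
        trend_slope=slope,
        trend_slope_ci=(slope - zcrit * se, slope + zcrit * se),
        params=fit.params,
        cov_params=fit.cov_params(),
        metadata={"design": DESIGN_NOTE, "weighted": weights is not None},
    )


def compare_metrics_wald(
    outcome,
    quintiles_a,
    quintiles_b,
    covariates=None,
    weights=None,
) -> tuple[float, float]:
    """Wald test comparing two metrics' fifth-quintile effects in one model.

    Both metrics' quintile dummies enter a joint logistic fit; the statistic
    (bA5 - bB5)^2 / (VA + VB - 2 Cov) is referred to chi-square(1).
    Returns (statistic, p_difference).
    """
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    da = _quintile_dummies(quintiles_a, "a_")
    db = _quintile_dummies(quintiles_b, "b_")
    if "a_q5" not in da.columns or "b_q5" not in db.columns:
        raise DegenerateInputError("fifth quintile empty for a metric: no comparison")
    X = pd.concat([da, db, _covariate_matrix(covariates, n)], axis=1)
    X.insert(0, "const", 1.0)
    _check_rank(X)  # identical quintile sets fail here with a diagnostic
    fit = _fit_logistic(y, X, weights)
    V = fit.cov_params()
    ba, bb = fit.params["a_q5"], fit.params["b_q5"]
    var = V.loc["a_q5", "a_q5"] + V.loc["b_q5", "b_q5"] - 2 * V.loc["a_q5", "b_q5"]
    stat = float((ba - bb) ** 2 / var)
    return stat, float(stats.chi2.sf(stat, df=1))


@dataclass(frozen=True)
class LinearTrendResult:
    deltas: dict  # {q: (delta_vs_Q1, lo, hi)} for q in 2..5
    p_trend: float
    trend_slope: float
    delta_q5_p: float
    params: pd.Series
    cov_params: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _fit_linear(y, X: pd.DataFrame, weights=None):
    _check_rank(X)
    if weights is not None:
        return sm.WLS(np.asarray(y, dtype=float), X, weights=np.asarray(weights, float)).fit()
    return sm.OLS(np.asarray(y, dtype=float), X).fit()


def adequacy_linear_trend(
    y,
    quintiles,
    covariates=None,
    weights=None,
    *,
    alpha: float = 0.05,
) -> LinearTrendResult:
    """Linear model of a continuous outcome (e.g. MPA) across quintiles.

    Reports each quintile's mean difference from Q1 with Wald CIs, the
    numeric-coded trend slope/p, and the Wald p for the first-to-fifth
    quintile delta.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = pd.concat([_quintile_dummies(quintiles, ""), _covariate_matrix(covariates, n)], axis=1)
    X.insert(0, "const", 1.0)
    fit = _fit_linear(y, X, weights)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    deltas = {}
    for j in (2, 3, 4, 5):
        if f"q{j}" not in fit.params:
            deltas[j] = (np.nan, np.nan, np.nan)
            continue
        b, se = float(fit.params[f"q{j}"]), float(fit.bse[f"q{j}"])
        deltas[j] = (b, b - zcrit * se, b + zcrit * se)
    if "q5" not in fit.params:
        raise DegenerateInputError("fifth quintile empty: no first-to-fifth delta")
    wald_q5 = float(stats.chi2.sf((fit.params["q5"] / fit.bse["q5"]) ** 2, df=1))

    code = (np.asarray(quintiles, dtype=int) - 1).astype(float)
    Xt = pd.concat([pd.DataFrame({"trend": code}), _covariate_matrix(covariates, n)], axis=1)
    Xt.insert(0, "const", 1.0)
    tfit = _fit_linear(y, Xt, weights)

    return LinearTrendResult(
        deltas=deltas,
        p_trend=float(tfit.pvalues["trend"]),
        trend_slope=float(tfit.params["trend"]),
        delta_q5_p=wald_q5,
        params=fit.params,
        cov_params=fit.cov_params(),
        metadata={"design": DESIGN_NOTE, "weighted": weights is not None},
    )


def compare_metrics_delta(
    y,
    quintiles_a,
    quintiles_b,
    covariates=None,
    weights=None,
) -> tuple[float, float]:
    """Wald comparison of two metrics' Q1-to-Q5 deltas in a joint linear model."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    da = _quintile_dummies(quintiles_a, "a_")
    db = _quintile_dummies(quintiles_b, "b_")
    if "a_q5" not in da.columns or "b_q5" not in db.columns:
        raise DegenerateInputError("fifth quintile empty for a metric: no comparison")
    X = pd.concat([da, db, _covariate_matrix(covariates, n)], axis=1)
    X.insert(0, "const", 1.0)
    fit = _fit_linear(y, X, weights)
    V = fit.cov_params()
    ba, bb = fit.params["a_q5"], fit.params["b_q5"]
    var = V.loc["a_q5", "a_q5"] + V.loc["b_q5", "b_q5"] - 2 * V.loc["a_q5", "b_q5"]
    stat = float((ba - bb) ** 2 / var)
    return stat, float(stats.chi2.sf(stat, df=1))
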
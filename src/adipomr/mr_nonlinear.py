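"""Stratified nonlinear Mendelian randomization (residual method).

To probe whether a genetic effect varies across the exposure distribution
without inducing collider bias, the exposure is first residualized on its
polygenic score; participants are then partitioned into K (default 20)
equal-size quantile strata of the residual, a Wald-ratio estimate is computed
within each stratum (exposure kept on the full-sample SD scale so stratum
estimates are comparable), and an OLS trend of the stratum estimates on the
stratum mean of the measured exposure tests linear variation, with an
added quadratic term and ANOVA F test for curvature.  Consistency of the
exposure-outcome association means neither the slope nor the curvature is
significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .mr_linear import (MRError, WeakInstrumentError, _scheme_cols,
                        _score_series, wald_score)


def residualize_exposure(table: pd.DataFrame, exposure: str, score,
                         scheme=None) -> pd.Series:
    """Exposure minus its OLS fit on the standardized score (+ covariates).

    Residuals keep natural exposure units and are exactly uncorrelated with
    the score in-sample (OLS orthogonality), which is what makes quantiles of
    the residual safe to stratify on.
    """
    score_std = _score_series(score)
    cols = _scheme_cols(scheme)
    used = table.dropna(subset=[exposure] + cols)
    x = used[exposure].to_numpy(dtype=float)
    if x.std(ddof=1) == 0:
        raise MRError(f"exposure {exposure} has zero variance")
    g = score_std.reindex(used["iid"].astype(str)).to_numpy(dtype=float)
    if np.isnan(g).any():
        raise MRError("some participants have no score")
    Z = used[cols].to_numpy(dtype=float) if cols else np.empty((len(used), 0))
    X = sm.add_constant(np.column_stack([g, Z]), has_constant="add")
    fit = sm.OLS(x, X).fit()
    return pd.Series(fit.resid, index=used.index, name=f"{exposure}_resid")


def stratify_quantiles(residuals: pd.Series, K: int = 20) -> pd.Series:
    """Rank-based assignment into K strata of size n/K (±1).

    Strata are indexed 1..K, non-decreasing in the residual; ties and the
    size remainder are resolved by stable input order.
    """
    r = np.asarray(residuals, dtype=float)
    n = len(r)
    if n < 10 * K:
        raise MRError(f"n = {n} < 10*K = {10 * K}; use a smaller K")
    if np.std(r) < 1e-10:
        raise MRError("residuals have (numerically) zero variance; cannot stratify")
    order = np.argsort(r, kind="stable")
    sizes = np.full(K, n // K)
    sizes[: n % K] += 1
    assignment = np.empty(n, dtype=int)
    start = 0
    for k, size in enumerate(sizes, start=1):
        assignment[order[start:start + size]] = k
        start += size
    return pd.Series(assignment, index=residuals.index, name="stratum")


@dataclass
class StratumEstimate:
    """Wald-ratio estimate within one exposure stratum."""

    index: int
    mean_exposure: float   # stratum mean of the measured exposure, natural units
    theta: float           # log-OR per (full-sample) SD of exposure
    se: float
    n: int
    flagged: bool = False  # weak instrument: excluded from the trend


def stratum_wald(table: pd.DataFrame, score, exposure: str,
                 assignment: pd.Series, scheme=None, outcome_col: str = "dead",
                 weak_t: float = 2.0) -> list:
    """Per-stratum Wald ratios on a common exposure scale.

    The exposure is standardized with the full-sample mean/SD so stratum
    estimates share units; strata failing the weak-instrument guard are
    returned flagged (with NaN estimate) rather than silently dropped.
    """
    import warnings

    used = table.loc[assignment.index]
    x_all = used[exposure].to_numpy(dtype=float)
    scale = (float(x_all.mean()), float(x_all.std(ddof=1)))
    out = []
    for k in sorted(assignment.unique()):
        sub = used[assignment == k]
        mean_exp = float(sub[exposure].mean())
        try:
            est = wald_score(score, sub, exposure, scheme=scheme,
                             outcome_col=outcome_col, weak_t=weak_t,
                             exposure_scale=scale)
            out.append(StratumEstimate(index=int(k), mean_exposure=mean_exp,
                                       theta=est.estimate, se=est.se, n=len(sub)))
        except (WeakInstrumentError, MRError) as exc:
            warnings.warn(f"stratum {k}: {exc}; excluded from trend")
            out.append(StratumEstimate(index=int(k), mean_exposure=mean_exp,
                                       theta=np.nan, se=np.nan, n=len(sub),
                                       flagged=True))
    return out


@dataclass
class TrendResult:
    """Variation of the stratum estimates across the exposure range."""

    slope: float
    slope_se: float
    slope_p: float
    quad: float
    quad_se: float
    f_stat: float
    p_nonlinearity: float
    consistent: bool
    n_strata: int
    alpha: float = 0.05


def trend_test(estimates, weighted: bool = False, regressor: str = "mean",
               alpha: float = 0.05) -> TrendResult:
    """Test constancy of the stratum Wald ratios.

    Regresses θ_k on the stratum mean exposure (``regressor="index"`` uses
    the stratum index instead), unweighted by default with an optional
    1/SE² weighting, then adds a quadratic term; the ANOVA F statistic
    compares the two fits.  Consistency requires both the slope p and the
    nonlinearity p to be >= ``alpha``.
    """
    usable = [e for e in estimates if not e.flagged and np.isfinite(e.theta)]
    if len(usable) < 4:
        raise MRError(f"need >= 4 usable strata, got {len(usable)}")
    theta = np.array([e.theta for e in usable])
    if regressor == "mean":
        x = np.array([e.mean_exposure for e in usable])
    elif regressor == "index":
        x = np.array([e.index for e in usable], dtype=float)
    else:
        raise MRError(f"unknown trend regressor {regressor!r}")
    if np.std(x) == 0:
        raise MRError("constant stratum means: trend regressors are collinear")
    w = 1.0 / np.array([e.se for e in usable]) ** 2 if weighted else np.ones(len(usable))

    xc = x - x.mean()  # center to decorrelate the linear and quadratic terms
    X1 = sm.add_constant(xc)
    X2 = sm.add_constant(np.column_stack([xc, xc**2]))
    fit1 = sm.WLS(theta, X1, weights=w).fit()
    fit2 = sm.WLS(theta, X2, weights=w).fit()
    df2 = len(usable) - 3
    if df2 < 1:
        raise MRError("too few strata for the quadratic comparison")
    if fit2.ssr <= 0:
        f_stat = 0.0 if fit1.ssr - fit2.ssr <= 1e-20 else np.inf
    else:
        f_stat = max(fit1.ssr - fit2.ssr, 0.0) / (fit2.ssr / df2)
    p_nl = float(stats.f.sf(f_stat, 1, df2))
    slope_p = float(fit1.pvalues[1])
    # a numerically flat fit (constant thetas) carries no trend signal even
    # though slope and SE are both round-off-level
    span = abs(float(fit1.params[1])) * float(np.ptp(x))
    if span < 1e-10 * (np.abs(theta).max() + 1e-300):
        slope_p = 1.0
    return TrendResult(
        slope=float(fit1.params[1]), slope_se=float(fit1.bse[1]), slope_p=slope_p,
        quad=float(fit2.params[2]), quad_se=float(fit2.bse[2]),
        f_stat=float(f_stat), p_nonlinearity=p_nl,
        consistent=bool(slope_p >= alpha and p_nl >= alpha),
        n_strata=len(usable), alpha=alpha,
    )


def strata_frame(estimates) -> pd.DataFrame:
    """Tidy, plot-ready table of stratum estimates with 95% CIs."""
    rows = []
    for e in estimates:
        rows.append(dict(stratum=e.index, mean_exposure=e.mean_exposure,
                         theta=e.theta, se=e.se,
                         l95=e.theta - 1.959964 * e.se,
                         u95=e.theta + 1.959964 * e.se,
                         n=e.n, flagged=e.flagged))
    return pd.DataFrame(rows)
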
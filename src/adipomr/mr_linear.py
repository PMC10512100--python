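"""One-sample linear Mendelian randomization estimators.

The primary estimator is the allelic score + Wald ratio: with the
standardized polygenic score G as single instrument, the exposure-instrument
association γ comes from a linear regression X ~ G (+ covariates), the
outcome-instrument association Γ from a logistic regression of case status
(matched case-control validation design, so effects are odds ratios), and the
causal estimate is θ = Γ/γ, reported as log-OR per SD of exposure with a
delta-method SE.  Per-variant sensitivity estimators — inverse-variance
weighting, MR-Egger, and the weighted median — consume (γ_j, Γ_j) summary
pairs computed in the same sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

Z95 = 1.959964


class MRError(RuntimeError):
    pass


def _score_series(score) -> pd.Series:
    """Accept a ScoreVector or a plain standardized Series keyed by iid."""
    from .scoring import ScoreVector

    if isinstance(score, ScoreVector):
        return score.std
    if isinstance(score, pd.Series):
        return score
    raise MRError(f"expected a ScoreVector or pandas Series, got {type(score)}")


def _scheme_cols(scheme) -> list:
    """Covariate columns from a CovariateScheme, an iterable, or None."""
    if scheme is None:
        return []
    cols = getattr(scheme, "columns", None)
    if cols is not None:
        return list(cols)
    return list(scheme)


class WeakInstrumentError(MRError):
    """The instrument-exposure association is too weak for a stable ratio."""


@dataclass
class MREstimate:
    """A causal effect estimate on the log-OR-per-SD scale."""

    method: str
    estimate: float
    se: float
    p: float
    n_variants: Optional[int] = None
    alpha: Optional[float] = None       # MR-Egger intercept
    alpha_se: Optional[float] = None
    alpha_p: Optional[float] = None
    gamma: Optional[float] = None       # instrument-exposure association
    gamma_se: Optional[float] = None
    n: Optional[int] = None

    @property
    def ci_low(self) -> float:
        return self.estimate - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.estimate + Z95 * self.se

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))

    def or_ci(self) -> tuple:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def _design(table: pd.DataFrame, cols, extra: np.ndarray) -> np.ndarray:
    Z = table[list(cols)].to_numpy(dtype=float) if cols else np.empty((len(table), 0))
    return sm.add_constant(np.column_stack([extra, Z]), has_constant="add")


def _logit_fit(y: np.ndarray, X: np.ndarray):
    try:
        return sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise MRError(f"logistic outcome model failed: {exc}") from exc


def _align(score_std: pd.Series, table: pd.DataFrame) -> tuple:
    idx = table["iid"].astype(str)
    s = score_std.reindex(idx)
    if s.isna().any():
        missing = int(s.isna().sum())
        raise MRError(f"{missing} participants have no score")
    return s.to_numpy(dtype=float)


def wald_score(score, table: pd.DataFrame, exposure: str, scheme=None,
               outcome_col: str = "dead", weak_t: float = 2.0,
               second_order: bool = False, exposure_scale=None) -> MREstimate:
    """Allelic-score Wald-ratio MR estimate for one exposure.

    ``score`` is a :class:`~adipomr.scoring.ScoreVector` or a standardized
    pandas Series keyed by iid.  The exposure is standardized in-sample so the
    estimate is a log-OR per SD; ``exposure_scale=(mean, sd)`` standardizes
    against an external reference instead (used by the stratified nonlinear
    MR so all strata share one scale).  Refuses to report when the instrument
    t statistic falls below ``weak_t``.
    """
    score_std = _score_series(score)
    cols = _scheme_cols(scheme)
    used = table.dropna(subset=[exposure, outcome_col] + cols)
    g = _align(score_std, used)
    x = used[exposure].to_numpy(dtype=float)
    mean, sd = exposure_scale if exposure_scale is not None else (x.mean(), x.std(ddof=1))
    if sd == 0:
        raise MRError(f"exposure {exposure} has zero variance")
    x_sd = (x - mean) / sd
    y = used[outcome_col].to_numpy(dtype=float)

    X = _design(used, cols, g)
    ols = sm.OLS(x_sd, X).fit()
    gamma, gamma_se = float(ols.params[1]), float(ols.bse[1])
    t_stat = gamma / gamma_se if gamma_se > 0 else np.inf
    if abs(t_stat) < weak_t:
        raise WeakInstrumentError(
            f"instrument t = {t_stat:.2f} < {weak_t} for {exposure}; "
            "refusing the Wald ratio")

    logit = _logit_fit(y, X)
    Gamma, Gamma_se = float(logit.params[1]), float(logit.bse[1])

    theta = Gamma / gamma
    if second_order:
        se = np.sqrt(Gamma_se**2 / gamma**2 + Gamma**2 * gamma_se**2 / gamma**4)
    else:
        se = Gamma_se / abs(gamma)
    p = 2 * stats.norm.sf(abs(theta) / se) if se > 0 else np.nan
    return MREstimate(method="wald_score", estimate=float(theta), se=float(se),
                      p=float(p), gamma=gamma, gamma_se=gamma_se, n=len(used))


def variant_summaries(dosages, table: pd.DataFrame, exposure: str, scheme=None,
                      outcome_col: str = "dead") -> pd.DataFrame:
    """Per-variant (γ_j, Γ_j) association pairs from individual-level data.

    For each variant, γ_j is the OLS coefficient of the standardized exposure
    on dosage (plus covariates) and Γ_j the logistic coefficient of case
    status on dosage; SEs come from the same fits.  One-sample approximation:
    both regressions use the same participants.
    """
    cols = _scheme_cols(scheme)
    used = table.dropna(subset=[exposure, outcome_col] + cols)
    idx = used["iid"].astype(str)
    D = dosages.frame.reindex(idx)
    if D.isna().all(axis=None):
        raise MRError("no dosage overlap with the table")
    x = used[exposure].to_numpy(dtype=float)
    x_sd = (x - x.mean()) / x.std(ddof=1)
    y = used[outcome_col].to_numpy(dtype=float)
    rows = []
    for vid in D.columns:
        d = D[vid].to_numpy(dtype=float)
        if np.isnan(d).any():
            d = np.where(np.isnan(d), np.nanmean(d), d)
        if d.std() == 0:
            continue
        X = _design(used, cols, d)
        ols = sm.OLS(x_sd, X).fit()
        logit = _logit_fit(y, X)
        rows.append(dict(variant_id=vid,
                         beta_exp=float(ols.params[1]), se_exp=float(ols.bse[1]),
                         beta_out=float(logit.params[1]), se_out=float(logit.bse[1])))
    return pd.DataFrame(rows)


def _check_summaries(summaries: pd.DataFrame) -> pd.DataFrame:
    required = {"variant_id", "beta_exp", "se_exp", "beta_out", "se_out"}
    missing = required - set(summaries.columns)
    if missing:
        raise MRError(f"variant summaries lack columns {sorted(missing)}")
    if (summaries[["se_exp", "se_out"]] <= 0).any(axis=None):
        raise MRError("variant summary SEs must be positive")
    return summaries


def ivw(summaries: pd.DataFrame) -> MREstimate:
    """Inverse-variance-weighted mean of per-variant Wald ratios.

    θ_IVW = Σ w_j θ_j / Σ w_j with θ_j = Γ_j/γ_j and w_j = γ_j²/SE(Γ_j)²;
    SE = 1/sqrt(Σ w_j).  Equivalent to the zero-intercept weighted regression
    of Γ on γ.  A single variant falls back to its plain Wald ratio.
    """
    s = _check_summaries(summaries)
    zero = s.loc[s["beta_exp"] == 0, "variant_id"].tolist()
    if zero:
        raise MRError(f"zero instrument-exposure association for variant(s) {zero}")
    gamma = s["beta_exp"].to_numpy(dtype=float)
    Gamma = s["beta_out"].to_numpy(dtype=float)
    se_out = s["se_out"].to_numpy(dtype=float)
    theta_j = Gamma / gamma
    w = gamma**2 / se_out**2
    if len(s) == 1:
        est, se = float(theta_j[0]), float(se_out[0] / abs(gamma[0]))
    else:
        est = float(np.sum(w * theta_j) / np.sum(w))
        se = float(1.0 / np.sqrt(np.sum(w)))
    p = 2 * stats.norm.sf(abs(est) / se)
    return MREstimate(method="ivw", estimate=est, se=se, p=float(p),
                      n_variants=len(s))


def mr_egger(summaries: pd.DataFrame) -> MREstimate:
    """MR-Egger: weighted regression Γ_j = α + θ γ_j with weights 1/SE(Γ_j)².

    Instrument-exposure associations are oriented positive (Γ re-signed
    accordingly).  The intercept α captures directional pleiotropy; under
    the InSIDE assumption the slope remains a consistent causal estimate.
    Requires at least three variants.
    """
    s = _check_summaries(summaries)
    if len(s) < 3:
        raise MRError(f"MR-Egger needs >= 3 variants, got {len(s)}")
    sign = np.sign(s["beta_exp"].to_numpy(dtype=float))
    if (sign == 0).any():
        raise MRError("zero instrument-exposure association")
    gamma = s["beta_exp"].to_numpy(dtype=float) * sign
    Gamma = s["beta_out"].to_numpy(dtype=float) * sign
    w = 1.0 / s["se_out"].to_numpy(dtype=float) ** 2
    X = sm.add_constant(gamma)
    fit = sm.WLS(Gamma, X, weights=w).fit()
    est, se = float(fit.params[1]), float(fit.bse[1])
    alpha, alpha_se = float(fit.params[0]), float(fit.bse[0])
    return MREstimate(method="egger", estimate=est, se=se,
                      p=float(fit.pvalues[1]), n_variants=len(s),
                      alpha=alpha, alpha_se=alpha_se, alpha_p=float(fit.pvalues[0]))


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    theta, w = theta[order], w[order]
    total = w.sum()
    if total <= 0:
        raise MRError("zero total weight in weighted median")
    s = (np.cumsum(w) - 0.5 * w) / total
    return float(np.interp(0.5, s, theta))


def weighted_median(summaries: pd.DataFrame, bootstrap_reps: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted-median MR estimate with a parametric-bootstrap SE.

    Ratio estimates are ordered and the estimate interpolates the cumulative
    normalized weights (midpoint convention) to 0.5; it is consistent when
    at least half the weight comes from valid instruments.  The SE resamples
    (γ_j, Γ_j) from their reported normal SEs.
    """
    s = _check_summaries(summaries)
    if len(s) < 3:
        raise MRError(f"weighted median needs >= 3 variants, got {len(s)}")
    gamma = s["beta_exp"].to_numpy(dtype=float)
    if (gamma == 0).any():
        raise MRError("zero instrument-exposure association")
    Gamma = s["beta_out"].to_numpy(dtype=float)
    se_g = s["se_exp"].to_numpy(dtype=float)
    se_G = s["se_out"].to_numpy(dtype=float)
    w = gamma**2 / se_G**2
    est = _weighted_median(Gamma / gamma, w)

    rng = np.random.default_rng([int(seed), 41])
    boot = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        gb = gamma + se_g * rng.standard_normal(len(s))
        Gb = Gamma + se_G * rng.standard_normal(len(s))
        gb = np.where(gb == 0, np.finfo(float).eps, gb)
        boot[b] = _weighted_median(Gb / gb, gb**2 / se_G**2)
    se = float(boot.std(ddof=1))
    p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else np.nan
    return MREstimate(method="weighted_median", estimate=est, se=se,
                      p=float(p), n_variants=len(s))


def interaction_test(score, table: pd.DataFrame, modifier: str = "sex",
                     scheme=None, outcome_col: str = "dead") -> float:
    """Wald p for the score × modifier product term in the outcome model."""
    score_std = _score_series(score)
    cols = _scheme_cols(scheme)
    cols = [c for c in cols if c != modifier]
    used = table.dropna(subset=[modifier, outcome_col] + cols)
    m = used[modifier].to_numpy(dtype=float)
    if np.unique(m).size < 2:
        raise MRError(f"modifier {modifier!r} is constant")
    if set(np.unique(m)) - {0.0, 1.0}:
        raise MRError(f"modifier {modifier!r} must be binary")
    g = _align(score_std, used)
    y = used[outcome_col].to_numpy(dtype=float)
    Z = used[cols].to_numpy(dtype=float) if cols else np.empty((len(used), 0))
    X = sm.add_constant(np.column_stack([g, m, g * m, Z]), has_constant="add")
    fit = _logit_fit(y, X)
    return float(fit.pvalues[3])
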
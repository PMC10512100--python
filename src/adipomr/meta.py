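"""Generic inverse-variance comparison of effect estimates.

Estimates enter on the log scale, either directly as (point, SE) or converted
from a printed ratio with its 95% CI via SE = (ln U - ln L)/(2 z).  Cochran's
Q under inverse-variance weights, its chi-square p, and I² = (Q - df)/Q
quantify heterogeneity across any labeled set of estimates; a pairwise mode
compares every pair in the set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

#: Normal quantile used for CI<->SE conversion at the 95% level.  The extra
#: digits over 1.96 matter when reproducing printed I² values from rounded CIs.
Z95 = 1.959964


class MetaError(ValueError):
    pass


class Estimate(NamedTuple):
    """A labeled log-scale effect estimate with its standard error."""

    label: str
    estimate: float
    se: float


def ci_to_se(point: float, lower: float, upper: float, level: float = 0.95):
    """Convert a ratio point estimate with CI to (log estimate, SE)."""
    if not (0 < lower < point < upper):
        raise MetaError(
            f"require 0 < L < point < U, got point={point}, L={lower}, U={upper}")
    z = stats.norm.ppf(0.5 + level / 2) if level != 0.95 else Z95
    log_est = np.log(point)
    se = (np.log(upper) - np.log(lower)) / (2 * z)
    return float(log_est), float(se)


def from_or_ci(label: str, point: float, lower: float, upper: float,
               level: float = 0.95) -> Estimate:
    est, se = ci_to_se(point, lower, upper, level)
    return Estimate(label=label, estimate=est, se=se)


@dataclass
class HeterogeneityResult:
    q: float
    df: int
    i2: float   # percent, clipped at 0
    p: float
    pooled: float
    labels: list

    def to_dict(self) -> dict:
        return dict(q=self.q, df=self.df, i2=self.i2, p=self.p,
                    pooled=self.pooled, labels=list(self.labels))


def _as_estimates(estimate_set) -> list:
    out = []
    for e in estimate_set:
        if isinstance(e, Estimate):
            out.append(e)
        else:
            label, est, se = e
            out.append(Estimate(str(label), float(est), float(se)))
    for e in out:
        if e.se <= 0:
            raise MetaError(f"estimate {e.label!r} has non-positive SE")
    return out


def cochran_q(estimate_set) -> HeterogeneityResult:
    """Cochran's Q, I² and heterogeneity p for k >= 2 log-scale estimates.

    Q = Σ w_i (x_i - m)² with w_i = 1/SE_i² and m the inverse-variance pooled
    mean; p is the upper chi-square tail on k-1 df; I² = max(0, (Q-df)/Q)
    reported as a percentage.
    """
    est = _as_estimates(estimate_set)
    if len(est) < 2:
        raise MetaError(f"need >= 2 estimates, got {len(est)}")
    x = np.array([e.estimate for e in est])
    w = 1.0 / np.array([e.se for e in est]) ** 2
    m = float(np.sum(w * x) / np.sum(w))
    q = float(np.sum(w * (x - m) ** 2))
    df = len(est) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    p = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q=q, df=df, i2=float(i2), p=p, pooled=m,
                               labels=[e.label for e in est])


def pairwise_q(estimate_set) -> pd.DataFrame:
    """Every pairwise Cochran's Q within the set (df = 1 each)."""
    est = _as_estimates(estimate_set)
    if len(est) < 2:
        raise MetaError("pairwise comparison needs >= 2 estimates")
    rows = []
    for i in range(len(est)):
        for j in range(i + 1, len(est)):
            r = cochran_q([est[i], est[j]])
            rows.append(dict(label_a=est[i].label, label_b=est[j].label,
                             q=r.q, i2=r.i2, p=r.p))
    return pd.DataFrame(rows)


def read_estimates_tsv(path) -> list:
    """Read a tidy TSV of (label, or, l95, u95) or (label, logor, se)."""
    df = pd.read_csv(path, sep="\t")
    if {"label", "logor", "se"} <= set(df.columns):
        return [Estimate(str(r.label), float(r.logor), float(r.se))
                for r in df.itertuples()]
    if {"label", "or", "l95", "u95"} <= set(df.columns):
        return [from_or_ci(str(row["label"]), float(row["or"]),
                           float(row["l95"]), float(row["u95"]))
                for _, row in df.iterrows()]
    raise MetaError(
        f"{path}: expected columns (label, or, l95, u95) or (label, logor, se)")
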
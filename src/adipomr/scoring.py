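"""Allelic scoring: polygenic scores from variant weights and dosages.

The polygenic risk score (PRS) of participant *i* is the weighted allele
count ``sum_j w_j * d_ij`` over the variants passing the association
p-value threshold, with the dosage flipped to ``2 - d`` whenever the counted
allele of the dosage file differs from the effect allele of the weight file.
Scores are standardized (mean 0, SD 1) in the sample being scored, which is
the convention for one-sample MR on the validation cohort; pass a reference
sample to standardize elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import DosageMatrix


class ScoringError(ValueError):
    pass


@dataclass
class ScoreVector:
    """Raw and standardized polygenic scores keyed by participant iid."""

    raw: pd.Series
    std: pd.Series
    n_variants: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score_raw": self.raw, "score_std": self.std})

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({"iid": self.std.index, "score_std": self.std.values})
        out.to_csv(path, sep="\t", index=False)


def compute_prs(dosages: DosageMatrix, weights: pd.DataFrame,
                p_threshold: float = 0.01,
                standardize_in=None) -> ScoreVector:
    """Score participants from per-allele weights.

    Only variants with ``pvalue < p_threshold`` contribute.  Missing dosages
    are mean-imputed per variant before scoring.  ``standardize_in`` may be an
    iid index giving the reference sample whose mean/SD standardize the score
    (defaults to the scored sample itself).
    """
    retained = weights[weights["pvalue"] < p_threshold]
    missing = [v for v in retained["variant_id"] if v not in dosages.frame.columns]
    if missing:
        raise ScoringError(f"variants absent from dosages: {missing[:10]}")

    if len(retained) == 0:
        raw = pd.Series(0.0, index=dosages.frame.index)
    else:
        D = dosages.frame[retained["variant_id"].tolist()].to_numpy(dtype=float)
        # per-variant mean imputation
        if np.isnan(D).any():
            col_mean = np.nanmean(D, axis=0)
            inds = np.where(np.isnan(D))
            D[inds] = np.take(col_mean, inds[1])
        w = retained["weight"].to_numpy(dtype=float).copy()
        flip = np.zeros(len(retained), dtype=bool)
        for k, (vid, ea) in enumerate(zip(retained["variant_id"], retained["effect_allele"])):
            counted = dosages.counted_allele.get(vid)
            if counted is None or not isinstance(ea, str) or not ea:
                raise ScoringError(f"cannot resolve allele orientation for {vid}")
            if ea != counted:
                flip[k] = True
        D = np.where(flip[None, :], 2.0 - D, D)
        raw = pd.Series(D @ w, index=dosages.frame.index)

    ref = raw if standardize_in is None else raw.loc[standardize_in]
    sd = ref.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ScoringError("degenerate score: zero variance, cannot standardize")
    std = (raw - ref.mean()) / sd
    return ScoreVector(raw=raw, std=std, n_variants=int(len(retained)))


@dataclass
class PRSValidation:
    """Association of a standardized score with its target trait."""

    beta: float           # trait units per SD of score
    se: float
    p: float
    r2_incremental: float
    n: int


def validate_prs(score: ScoreVector, table: pd.DataFrame, trait: str,
                 covariates=()) -> PRSValidation:
    """Regress the trait on the standardized score (plus covariates).

    Reports the slope in trait units per score SD, its SE and p, and the
    incremental R² of the score over the covariate-only model.
    """
    idx = table.set_index(table["iid"].astype(str))
    common = score.std.index.astype(str).intersection(idx.index)
    if len(common) < 10:
        raise ScoringError(f"only {len(common)} overlapping iids; need >= 10")
    y = idx.loc[common, trait].to_numpy(dtype=float)
    s = score.std.loc[common].to_numpy(dtype=float)
    Z = idx.loc[common, list(covariates)].to_numpy(dtype=float) if covariates else \
        np.empty((len(common), 0))
    X_full = sm.add_constant(np.column_stack([s, Z]), has_constant="add")
    fit = sm.OLS(y, X_full).fit()
    if Z.shape[1]:
        base = sm.OLS(y, sm.add_constant(Z, has_constant="add")).fit()
        r2_inc = fit.rsquared - base.rsquared
    else:
        r2_inc = fit.rsquared
    return PRSValidation(beta=float(fit.params[1]), se=float(fit.bse[1]),
                         p=float(fit.pvalues[1]), r2_incremental=float(r2_inc),
                         n=int(len(common)))
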
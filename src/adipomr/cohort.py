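"""Cohort assembly: exclusion filters, cause-of-death classification,
stratification, and the propensity-matched case-control partition.

The filter ordering mirrors the study design: rows with incomplete required
phenotypes are removed first, then rows with extreme BMI (strictly below 15 or
above 50), then prevalent cases of the outcome disease; the
:class:`ExclusionLog` telescopes exactly through these steps.  The matched
partition pairs every death 1:1 with a living control on the propensity score
built from age, sex, and the first ten genetic principal components — the
pairs form the validation (MR) cohort, everyone else the discovery cohort.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_REQUIRED_FIELDS = ("age", "sex", "bmi", "fmi", "whr")

#: Default chapter-level ICD-10 mapping: (category, start code, end code).
DEFAULT_ICD_MAPPING = (
    ("cancer", "C00", "C97"),
    ("cvd", "I00", "I99"),
    ("respiratory", "J00", "J99"),
)

_PREVALENT_COLS = {"cvd": "prev_cvd", "cancer": "prev_cancer",
                   "respiratory": "prev_resp"}

_ICD_RE = re.compile(r"^([A-Za-z])(\d{1,3})")


class CohortError(ValueError):
    pass


@dataclass
class ExclusionLog:
    """Telescoping participant counts through the exclusion filters."""

    initial: int = 0
    missing_removed: int = 0
    extreme_bmi_removed: int = 0
    prevalent_removed: int = 0
    final: int = 0

    def telescopes(self) -> bool:
        return (self.initial - self.missing_removed - self.extreme_bmi_removed
                - self.prevalent_removed) == self.final

    def to_dict(self) -> dict:
        return dict(initial=self.initial, missing_removed=self.missing_removed,
                    extreme_bmi_removed=self.extreme_bmi_removed,
                    prevalent_removed=self.prevalent_removed, final=self.final)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def apply_exclusions(table: pd.DataFrame, bmi_bounds=(15.0, 50.0),
                     required_fields=DEFAULT_REQUIRED_FIELDS,
                     exclude_prevalent_for=None):
    """Apply the complete-case, extreme-BMI, and prevalent-disease filters.

    Order: rows missing any required field are removed first, then rows with
    BMI strictly below ``bmi_bounds[0]`` or strictly above ``bmi_bounds[1]``
    (boundary values are retained), then prevalent cases of
    ``exclude_prevalent_for`` (an outcome label, ``"any"`` for all three
    disease groups, or None to skip).  Returns the filtered table and an
    :class:`ExclusionLog`.
    """
    lo, hi = bmi_bounds
    if lo > hi:
        raise CohortError(f"bmi_bounds must be ordered, got {bmi_bounds}")
    unknown = [c for c in required_fields if c not in table.columns]
    if unknown:
        raise CohortError(
            f"unknown required field(s) {unknown}; available columns: "
            f"{sorted(table.columns)}")

    log = ExclusionLog(initial=len(table))
    kept = table.dropna(subset=list(required_fields))
    log.missing_removed = log.initial - len(kept)

    in_bounds = (kept["bmi"] >= lo) & (kept["bmi"] <= hi)
    log.extreme_bmi_removed = int((~in_bounds).sum())
    kept = kept[in_bounds]

    if exclude_prevalent_for is not None:
        if exclude_prevalent_for == "any":
            cols = list(_PREVALENT_COLS.values())
        elif exclude_prevalent_for in _PREVALENT_COLS:
            cols = [_PREVALENT_COLS[exclude_prevalent_for]]
        elif exclude_prevalent_for in ("all_cause", "other"):
            cols = list(_PREVALENT_COLS.values())
        else:
            raise CohortError(
                f"unknown outcome label {exclude_prevalent_for!r}; expected one of "
                f"{sorted(_PREVALENT_COLS) + ['any', 'all_cause', 'other']}")
        cols = [c for c in cols if c in kept.columns]
        if cols:
            prevalent = kept[cols].fillna(0).astype(float).sum(axis=1) > 0
            log.prevalent_removed = int(prevalent.sum())
            kept = kept[~prevalent]
    log.final = len(kept)
    return kept.copy(), log


def classify_cause(icd10_code, mapping=DEFAULT_ICD_MAPPING) -> str:
    """Map an ICD-10 code to {cancer, cvd, respiratory, other} by code range."""
    if icd10_code is None or (isinstance(icd10_code, float) and np.isnan(icd10_code)):
        warnings.warn("empty ICD-10 code classified as 'other'")
        return "other"
    m = _ICD_RE.match(str(icd10_code).strip())
    if m is None:
        warnings.warn(f"malformed ICD-10 code {icd10_code!r} classified as 'other'")
        return "other"
    letter, num = m.group(1).upper(), int(m.group(2)[:2])
    for category, start, end in mapping:
        s, e = _ICD_RE.match(start), _ICD_RE.match(end)
        if s is None or e is None:
            raise CohortError(f"malformed mapping range {start!r}-{end!r}")
        if letter == s.group(1).upper() == e.group(1).upper() and \
                int(s.group(2)) <= num <= int(e.group(2)):
            return category
    return "other"


def classify_causes(codes: pd.Series, mapping=DEFAULT_ICD_MAPPING) -> pd.Series:
    """Vectorized :func:`classify_cause` over a series (NaN stays NaN)."""
    out = pd.Series(index=codes.index, dtype=object)
    mask = codes.notna()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out[mask] = [classify_cause(c, mapping) for c in codes[mask]]
    return out


@dataclass
class MatchResult:
    """1:1 propensity-matched validation set and the discovery remainder."""

    validation_iids: list
    discovery_iids: list
    n_cases: int
    smd_before: dict = field(default_factory=dict)
    smd_after: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(validation_iids=list(self.validation_iids),
                    discovery_iids=list(self.discovery_iids),
                    n_cases=self.n_cases, smd_before=self.smd_before,
                    smd_after=self.smd_after)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


PS_COVARIATES = ("age", "sex") + tuple(f"pc{i}" for i in range(1, 11))


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def _propensity_logit(table: pd.DataFrame, case: np.ndarray,
                      covariates) -> np.ndarray:
    X = table[list(covariates)].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.any():
        return np.zeros(len(table))  # degenerate: identical covariates
    X = sm.add_constant(X[:, keep], has_constant="add")
    try:
        fit = sm.Logit(case, X).fit(disp=0, maxiter=200)
        eta = X @ fit.params
    except Exception:  # separation / singularity: ridge-regularized fallback
        fit = sm.Logit(case, X).fit_regularized(alpha=1.0, disp=0, maxiter=500)
        eta = X @ fit.params
    return np.asarray(eta, dtype=float)


def propensity_match_split(table: pd.DataFrame, seed: int,
                           case_col: str = "dead",
                           covariates=PS_COVARIATES,
                           caliper: float | None = None) -> MatchResult:
    """Split the cohort into a matched validation set and a discovery set.

    Fits case status on the matching covariates by logistic regression, then
    greedily pairs each case (in random order under ``seed``) with the
    nearest unused control on the logit propensity scale, without
    replacement.  Distance ties break toward the lowest control iid.  With a
    ``caliper`` (in SDs of the logit score), cases with no control inside the
    caliper are left unmatched and stay in the discovery set.
    """
    case = table[case_col].to_numpy(dtype=float)
    if set(np.unique(case)) - {0.0, 1.0}:
        raise CohortError(f"{case_col} must be binary 0/1")
    n_cases, n_controls = int(case.sum()), int((1 - case).sum())
    if n_cases < 1 or n_controls < 1:
        raise CohortError(f"need >= 1 case and >= 1 control, got {n_cases}/{n_controls}")
    if n_controls < n_cases:
        raise CohortError(
            f"fewer eligible controls ({n_controls}) than cases ({n_cases})")

    eta = _propensity_logit(table, case, covariates)
    iid = table["iid"].astype(str).to_numpy()
    case_idx = np.flatnonzero(case == 1)
    ctrl_idx = np.flatnonzero(case == 0)

    # controls sorted by (logit, iid) so equal-distance ties resolve to low iid
    order = np.lexsort((iid[ctrl_idx], eta[ctrl_idx]))
    ctrl_sorted = ctrl_idx[order]
    ctrl_eta = eta[ctrl_sorted]
    ctrl_iid = iid[ctrl_sorted]
    nc = len(ctrl_sorted)

    # linked list over alive controls plus a union-find "next alive >= i" jump;
    # index nc acts as a right sentinel
    nxt = np.arange(1, nc + 2)          # nxt[i] = next alive node (or sentinel)
    prv = np.arange(-1, nc)             # prv[i] = previous alive node (-1 = none)
    parent = np.arange(nc + 1)

    def find_right(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    max_dist = np.inf
    if caliper is not None:
        sd = eta.std(ddof=1)
        max_dist = caliper * (sd if sd > 0 else 1.0)

    rng = np.random.default_rng([int(seed), 21])
    matched_cases, matched_ctrls = [], []
    for ci in rng.permutation(case_idx):
        target = eta[ci]
        pos = int(np.searchsorted(ctrl_eta, target))
        right = find_right(min(pos, nc))
        left = prv[right]
        cand = []
        if left >= 0:
            cand.append(int(left))
        if right < nc:
            cand.append(int(right))
        if not cand:
            raise CohortError("ran out of controls during matching")
        best = min(cand, key=lambda j: (abs(ctrl_eta[j] - target), ctrl_iid[j]))
        if abs(ctrl_eta[best] - target) > max_dist:
            continue  # caliper: case left unmatched
        matched_cases.append(ci)
        matched_ctrls.append(ctrl_sorted[best])
        # splice out of the linked list and the union-find structure
        p, q = int(prv[best]), int(nxt[best])
        if p >= 0:
            nxt[p] = q
        prv[q] = p
        parent[best] = min(q, nc)

    val = np.concatenate([matched_cases, matched_ctrls]).astype(int) if matched_cases else np.array([], int)
    val_mask = np.zeros(len(table), dtype=bool)
    val_mask[val] = True

    smd_before, smd_after = {}, {}
    mc, mt = np.asarray(matched_cases, int), np.asarray(matched_ctrls, int)
    for cov in covariates:
        x = table[cov].to_numpy(dtype=float)
        smd_before[cov] = _smd(x[case == 1], x[case == 0])
        if len(mc):
            smd_after[cov] = _smd(x[mc], x[mt])
    return MatchResult(
        validation_iids=sorted(iid[val_mask].tolist()),
        discovery_iids=sorted(iid[~val_mask].tolist()),
        n_cases=len(matched_cases),
        smd_before=smd_before, smd_after=smd_after,
    )


def stratify(table: pd.DataFrame, scheme: str, age_bins=None) -> dict:
    """Partition the cohort by sex, empirical age tertiles, or menopausal age.

    ``menopause_age`` splits female participants at age 52 and younger
    (premenopausal age) versus 53 and older; it errors on a table with no
    females.  Returned subsets are disjoint and (except for the females-only
    menopause scheme) cover the input table.
    """
    if scheme == "sex":
        return {"male": table[table["sex"] == 1].copy(),
                "female": table[table["sex"] == 0].copy()}
    if scheme == "menopause_age":
        females = table[table["sex"] == 0]
        if len(females) == 0:
            raise CohortError("menopause_age stratification needs female participants")
        pre = females[females["age"] <= 52]
        post = females[females["age"] > 52]
        return {"premenopausal_age": pre.copy(), "postmenopausal_age": post.copy()}
    if scheme == "age_tertiles":
        if age_bins is None:
            age_bins = np.quantile(table["age"], [1 / 3, 2 / 3])
        lo, hi = float(age_bins[0]), float(age_bins[1])
        a = table["age"]
        return {
            f"age<={lo:.1f}": table[a <= lo].copy(),
            f"age({lo:.1f},{hi:.1f}]": table[(a > lo) & (a <= hi)].copy(),
            f"age>{hi:.1f}": table[a > hi].copy(),
        }
    raise CohortError(f"unknown stratification scheme {scheme!r}")
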
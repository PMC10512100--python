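"""Synthetic biobank-like cohort generator.

Every downstream stage of the package (filtering, scoring, proportional-hazards
fits, linear and nonlinear Mendelian randomization) is testable against a known
ground truth produced here.  The generator emulates:

* an additive genetic architecture — independent biallelic variants with
  dosages drawn binomial(2, MAF) — driving three correlated adiposity
  exposures (BMI, FMI, WHR), each with a polygenic score explaining a
  configurable fraction of exposure variance;
* a J-shaped exposure→log-hazard map for BMI/FMI (interior nadir) and a
  monotone map for WHR, on top of age and sex effects;
* censored survival under a constant (exponential) individual hazard with
  administrative censoring, and four cause-of-death categories coded as
  chapter-representative ICD-10 strings;
* completely-at-random missingness in phenotype columns, a small rate of
  extreme BMI values, and prevalent-disease flags.

A single integer seed is fanned out to per-stage child generators through
fixed offsets so each stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CAUSES, EXPOSURES, ConfigError, HazardShape, SimConfig
from .io import DosageMatrix, write_phenotypes, write_truth, write_weights

# ICD-10 codes sampled per cause category (chapter-representative strings).
_CAUSE_CODES = {
    "cancer": ["C18", "C34", "C50", "C61"],
    "cvd": ["I21", "I25", "I50", "I63"],
    "respiratory": ["J18", "J44", "J45"],
    "other": ["E11", "G30", "K70", "N18"],
}

# Fixed offsets fanning the global seed out to sub-generators.
_STAGE = {"genotypes": 1, "weights": 2, "exposures": 3, "covariates": 4,
          "mortality": 5, "missing": 6, "extreme": 7, "prevalent": 8}

_ALLELES = np.array(list("ACGT"))


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort; stored verbatim, never mutated.

    ``per_sd_log_effect`` holds the true per-SD log-hazard/log-odds effect for
    linear maps (None for J-shapes), ``nadir`` the true nadir in natural units
    for quadratic maps, ``weights`` the true per-allele variant weights in
    natural exposure units, and ``prs_r2`` the targeted variance explained.
    """

    per_sd_log_effect: dict = field(default_factory=dict)
    nadir: dict = field(default_factory=dict)
    weights: dict = field(default_factory=dict)
    prs_r2: float = 0.0
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_sd_log_effect": self.per_sd_log_effect,
            "nadir": self.nadir,
            "weights": self.weights,
            "prs_r2": self.prs_r2,
            "config": self.config,
        }


@dataclass
class SimulatedCohort:
    phenotypes: pd.DataFrame
    dosages: DosageMatrix
    weights: dict  # exposure -> weights DataFrame (variant_id, effect_allele, weight, pvalue)
    scores: pd.DataFrame  # true (noise-free) standardized genetic scores per exposure
    truth: TruthRecord


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STAGE[stage]])


def simulate_genotypes(n: int, m: int, mafs, seed: int) -> DosageMatrix:
    """Draw an n×m dosage matrix with entries binomial(2, MAF).

    ``mafs`` may be a scalar, a length-m vector, or a (lo, hi) range from
    which per-variant frequencies are drawn uniformly.  Variants are
    independent (no linkage disequilibrium).
    """
    rng = _rng(seed, "genotypes")
    if np.isscalar(mafs):
        maf = np.full(m, float(mafs))
    else:
        mafs = np.asarray(mafs, dtype=float)
        if mafs.shape == (2,) and m != 2:
            maf = rng.uniform(mafs[0], mafs[1], size=m)
        else:
            if mafs.shape != (m,):
                raise ConfigError(f"expected {m} allele frequencies, got shape {mafs.shape}")
            maf = mafs
    if m and ((maf <= 0).any() or (maf > 0.5).any()):
        raise ConfigError("allele frequencies must lie in (0, 0.5]")
    dosages = rng.binomial(2, maf, size=(n, m)).astype(float)
    ids = [f"rs{i + 1}" for i in range(m)]
    counted = {vid: a for vid, a in zip(ids, rng.choice(_ALLELES, size=m))}
    frame = pd.DataFrame(dosages, columns=ids,
                         index=pd.Index([f"id{i + 1}" for i in range(n)], name="iid"))
    return DosageMatrix(frame=frame, counted_allele=counted)


def simulate_exposures(dosages: DosageMatrix, config: SimConfig):
    """Build BMI/FMI/WHR from genetic scores plus correlated environment.

    Each exposure is ``sqrt(h2) * score_std + sqrt(1 - h2) * noise_std`` on the
    latent (SD-unit) scale, so the score explains ``prs_variance_explained``
    of exposure variance by construction; the three noise components share the
    ``exposure_corr`` correlation.  Latents are then affinely mapped to the
    natural scales in ``config.exposure_scales``.

    Returns ``(exposures, scores, truth)`` where ``scores`` are the true
    standardized genetic scores and ``truth`` a :class:`TruthRecord` carrying
    the per-allele weights in natural exposure units.
    """
    config.validate()
    n, m = dosages.frame.shape
    h2 = config.prs_variance_explained
    corr = config.corr_matrix()
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ConfigError("exposure_corr is not positive-definite") from exc

    w_rng = _rng(config.seed, "weights")
    e_rng = _rng(config.seed, "exposures")
    D = dosages.frame.to_numpy()
    Dc = D - D.mean(axis=0, keepdims=True) if m else D

    noise = e_rng.standard_normal(size=(n, 3)) @ chol.T

    exposures = pd.DataFrame(index=dosages.frame.index.copy())
    scores = pd.DataFrame(index=dosages.frame.index.copy())
    truth = TruthRecord(prs_r2=h2, config=config.to_dict())
    for k, exp in enumerate(EXPOSURES):
        w = w_rng.standard_normal(m)
        g = Dc @ w if m else np.zeros(n)
        sd_g = g.std(ddof=0)
        if sd_g > 0 and h2 > 0:
            g_std = g / sd_g
            latent = np.sqrt(h2) * g_std + np.sqrt(1 - h2) * noise[:, k]
            # per-allele weight in natural exposure units
            scale = config.exposure_scales[exp][1] * np.sqrt(h2) / sd_g
        else:
            g_std = g / sd_g if sd_g > 0 else np.zeros(n)
            latent = noise[:, k]
            scale = 0.0
        mean, sd = config.exposure_scales[exp]
        exposures[exp] = mean + sd * latent
        scores[exp] = g_std
        truth.weights[exp] = {vid: float(scale * wj)
                              for vid, wj in zip(dosages.variant_ids, w)}
        shape = config.hazard_shape.get(exp, HazardShape())
        truth.per_sd_log_effect[exp] = shape.per_sd_log_effect(sd)
        if shape.kind == "quadratic":
            truth.nadir[exp] = shape.nadir
    return exposures, scores, truth


def simulate_covariates(n: int, seed: int, bmi_sd=None) -> pd.DataFrame:
    """Age, sex, genetic PCs, and lifestyle/clinical covariates.

    ``bmi_sd`` (standardized BMI) mildly drives blood pressure, triglycerides
    and diabetes so covariate adjustment is non-trivial in fitted models.
    """
    rng = _rng(seed, "covariates")
    if bmi_sd is None:
        bmi_sd = np.zeros(n)
    bmi_sd = np.asarray(bmi_sd, dtype=float)
    df = pd.DataFrame(index=pd.RangeIndex(n))
    df["age"] = np.clip(rng.normal(56.9, 8.0, n), 40.0, 70.0)
    df["sex"] = rng.binomial(1, 0.457, n)
    for i in range(1, 11):
        df[f"pc{i}"] = rng.standard_normal(n)
    df["smoking"] = rng.binomial(1, 0.45, n)
    df["diabetes"] = rng.binomial(1, _sigmoid(-3.2 + 0.5 * bmi_sd), n)
    df["alcohol"] = rng.gamma(2.0, 4.0, n)
    df["tc"] = rng.normal(5.7, 1.1, n)
    df["ldl"] = rng.normal(3.6, 0.85, n)
    df["hdl"] = np.maximum(rng.normal(1.45, 0.38, n) - 0.08 * bmi_sd, 0.4)
    df["tg"] = np.exp(rng.normal(0.4, 0.45, n) + 0.12 * bmi_sd)
    df["sbp"] = rng.normal(138, 18, n) + 2.5 * bmi_sd
    df["dbp"] = rng.normal(82, 10, n) + 1.5 * bmi_sd
    df["prev_cvd"] = rng.binomial(1, 0.05, n)
    df["prev_cancer"] = rng.binomial(1, 0.04, n)
    df["prev_resp"] = rng.binomial(1, 0.03, n)
    return df


def simulate_mortality(exposures: pd.DataFrame, covariates: pd.DataFrame,
                       config: SimConfig, seed: int) -> pd.DataFrame:
    """Draw censored survival outcomes from an exponential individual hazard.

    log hazard = baseline + age/sex terms + Σ exposure map contributions;
    event times are exponential with that rate and administratively censored
    at ``followup_years``.  Deaths get an ICD-10-style cause code sampled from
    ``cause_mix``.
    """
    config.validate()
    if config.followup_years <= 0:
        raise ConfigError("followup_years must be positive")
    n = len(exposures)
    rng = _rng(seed, "mortality")
    log_h = np.full(n, config.baseline_log_hazard)
    log_h = log_h + config.age_log_hazard * (covariates["age"].to_numpy() - 56.9)
    log_h = log_h + config.sex_log_hazard * covariates["sex"].to_numpy()
    for exp, shape in config.hazard_shape.items():
        x = exposures[exp].to_numpy()
        mean, sd = config.exposure_scales[exp]
        log_h = log_h + shape.log_hazard(x, (x - mean) / sd)
    rate = np.exp(log_h)
    t_event = rng.exponential(1.0 / rate)
    dead = (t_event < config.followup_years).astype(int)
    time_years = np.minimum(t_event, config.followup_years)

    probs = np.array([config.cause_mix.get(c, 0.0) for c in CAUSES])
    cause_idx = rng.choice(len(CAUSES), size=n, p=probs)
    codes = np.array([
        _CAUSE_CODES[CAUSES[i]][rng.integers(len(_CAUSE_CODES[CAUSES[i]]))]
        for i in cause_idx
    ], dtype=object)
    out = pd.DataFrame(index=exposures.index)
    out["time_years"] = time_years
    out["dead"] = dead
    out["cause_icd10"] = np.where(dead == 1, codes, None)
    return out


def simulate_case_status(x_sd, log_or: float, seed: int, intercept: float = 0.0) -> np.ndarray:
    """Bernoulli case status with logit = intercept + log_or * x_sd.

    Case-control outcome generator: the true effect is an exact log odds
    ratio per SD of the exposure, which is what the Wald-ratio estimators
    target in the matched validation design.
    """
    rng = np.random.default_rng([int(seed), 11])
    p = _sigmoid(intercept + log_or * np.asarray(x_sd, dtype=float))
    return rng.binomial(1, p)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def _marginal_pvalues(dosages: DosageMatrix, x: np.ndarray) -> np.ndarray:
    """Per-variant association p of exposure on dosage (marginal OLS t-test)."""
    from scipy import stats

    D = dosages.frame.to_numpy()
    n, m = D.shape
    if m == 0:
        return np.zeros(0)
    Dc = D - D.mean(axis=0)
    xc = x - x.mean()
    sd = Dc.std(axis=0) * xc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(sd > 0, (Dc * xc[:, None]).mean(axis=0) / sd, 0.0)
        r = np.clip(r, -0.999999, 0.999999)
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Run every stage and assemble the phenotype table plus side files."""
    config.validate()
    n, m = config.n_participants, config.n_variants
    dosages = simulate_genotypes(n, m, config.maf_range, config.seed)
    exposures, scores, truth = simulate_exposures(dosages, config)
    bmi_mean, bmi_sd = config.exposure_scales["bmi"]
    covars = simulate_covariates(n, config.seed,
                                 bmi_sd=(exposures["bmi"].to_numpy() - bmi_mean) / bmi_sd)
    covars.index = exposures.index
    survival = simulate_mortality(exposures, covars, config, config.seed)

    pheno = pd.concat([covars, exposures, survival], axis=1)
    pheno.insert(0, "iid", pheno.index)

    # extreme BMI injection (disjoint from missingness, applied first)
    ext_rng = _rng(config.seed, "extreme")
    extreme = ext_rng.random(n) < config.extreme_bmi_rate
    if extreme.any():
        k = int(extreme.sum())
        low = ext_rng.random(k) < 0.5
        vals = np.where(low, ext_rng.uniform(11.5, 14.5, k), ext_rng.uniform(50.5, 62.0, k))
        pheno.loc[extreme, "bmi"] = vals

    # MCAR missingness in a few required phenotype columns, sparing extreme rows
    miss_rng = _rng(config.seed, "missing")
    missable = ["fmi", "whr", "tc", "alcohol"]
    miss_rows = (miss_rng.random(n) < config.missing_rate) & ~extreme
    if miss_rows.any():
        which = miss_rng.integers(0, len(missable), size=int(miss_rows.sum()))
        rows = np.flatnonzero(miss_rows)
        for col_idx in range(len(missable)):
            sel = rows[which == col_idx]
            pheno.iloc[sel, pheno.columns.get_loc(missable[col_idx])] = np.nan

    # weights files: true per-allele weights + honest marginal association p
    weights = {}
    for exp in EXPOSURES:
        w = truth.weights[exp]
        pvals = _marginal_pvalues(dosages, exposures[exp].to_numpy())
        weights[exp] = pd.DataFrame({
            "variant_id": dosages.variant_ids,
            "effect_allele": [dosages.counted_allele[v] for v in dosages.variant_ids],
            "weight": [w[v] for v in dosages.variant_ids],
            "pvalue": pvals,
        })
    return SimulatedCohort(phenotypes=pheno.reset_index(drop=True), dosages=dosages,
                           weights=weights, scores=scores, truth=truth)


#: Named fixture presets.  "tiny" is a smoke fixture with a strong genetic
#: signal and a high event rate so every stage has data to chew on; "null"
#: severs the exposure→mortality link; "paper_like" is the default 50k cohort.
FIXTURES = {
    "tiny": dict(n_participants=200, n_variants=50, prs_variance_explained=0.5,
                 baseline_log_hazard=-4.2, missing_rate=0.02, extreme_bmi_rate=0.0),
    "null": dict(n_participants=2000, n_variants=50,
                 hazard_shape={e: HazardShape() for e in EXPOSURES}),
    "paper_like": dict(),
}


def make_fixture(name: str, out_dir, seed: int = 0, **overrides):
    """Simulate a named fixture and write its files to ``out_dir``.

    Writes ``phenotypes.tsv``, ``dosages.raw``, one ``weights_<exposure>.tsv``
    per exposure, and ``truth.json``; returns a dict of paths.
    """
    if name not in FIXTURES:
        raise ConfigError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    params = dict(FIXTURES[name])
    params.update(overrides)
    params["seed"] = seed
    config = SimConfig(**params)
    sim = simulate_cohort(config)
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {"phenotypes": out / "phenotypes.tsv", "dosages": out / "dosages.raw",
                 "truth": out / "truth.json"}
        write_phenotypes(sim.phenotypes, paths["phenotypes"])
        sim.dosages.to_raw(paths["dosages"])
        for exp, wdf in sim.weights.items():
            paths[f"weights_{exp}"] = out / f"weights_{exp}.tsv"
            write_weights(wdf, paths[f"weights_{exp}"])
        write_truth(sim.truth.to_dict(), paths["truth"])
    except OSError as exc:
        raise OSError(f"failed writing fixture {name!r} under {out}: {exc}") from exc
    return {k: str(v) for k, v in paths.items()}
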
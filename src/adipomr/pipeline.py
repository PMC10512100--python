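"""End-to-end orchestration: simulate → filter → match → score →
observational → linear MR → nonlinear MR → heterogeneity.

:func:`run_all` executes every stage under one :class:`~adipomr.config.RunConfig`
and writes tidy outputs (a Table-1 analog of epidemiological HRs and MR ORs,
a cause-specific Table-2 analog, stratum-estimate plots for the nonlinear MR,
heterogeneity JSON, exclusion and matching logs) plus a run log recording
seeds, versions, and every threshold used.  Stages are also exposed
individually through the CLI so partial reruns consume the documented file
formats.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (apply_exclusions, classify_causes, propensity_match_split,
                     stratify)
from .config import CAUSES, EXPOSURES, RunConfig
from .io import DosageMatrix, read_dosages, read_phenotypes, read_weights
from .meta import Estimate, cochran_q, from_or_ci, pairwise_q
from .mr_linear import (MRError, WeakInstrumentError, interaction_test, ivw,
                        mr_egger, variant_summaries, wald_score,
                        weighted_median)
from .mr_nonlinear import (residualize_exposure, strata_frame, stratify_quantiles,
                           stratum_wald, trend_test)
from .observational import (CovariateScheme, FitError, estimate_nadir, fit_ph,
                            test_nonlinearity)
from .scoring import compute_prs, validate_prs
from .synth import simulate_cohort

log = logging.getLogger("adipomr")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    out_dir: Path
    exclusion_log: object = None
    match: object = None
    observational: pd.DataFrame = None
    mr: pd.DataFrame = None
    nlmr_strata: pd.DataFrame = None
    nlmr_trend: pd.DataFrame = None
    heterogeneity: dict = field(default_factory=dict)
    table1: pd.DataFrame = None
    table2: pd.DataFrame = None
    prs_validation: pd.DataFrame = None


def _config_hash(config: RunConfig) -> str:
    import dataclasses

    d = dataclasses.asdict(config)
    d.pop("out_dir", None)  # the analysis identity is path-independent
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _scheme_without(scheme: CovariateScheme, drop: str) -> CovariateScheme:
    return CovariateScheme(name=scheme.name,
                           columns=[c for c in scheme.columns if c != drop])


def _write(df: pd.DataFrame, path: Path, meta_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# adipomr {__version__} config={meta_hash} schema=1\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_all(config: RunConfig) -> PipelineResult:
    """Run every stage in order; failures abort naming the stage, keeping
    the outputs already written."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run_log.txt", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    meta_hash = _config_hash(config)
    res = PipelineResult(out_dir=out)
    try:
        log.info("adipomr %s run, seed=%d, config hash %s", __version__,
                 config.seed, meta_hash)
        log.info("thresholds: PRS p<%g, nonlinearity F>%g, alpha=%g, K=%d",
                 config.p_threshold, config.f_threshold, config.alpha,
                 config.n_quantiles)
        with open(out / "run_meta.json", "w") as f:
            json.dump({"version": __version__, "seed": config.seed,
                       "config_hash": meta_hash}, f, indent=2)

        # ---- stage: inputs -------------------------------------------------
        stage = "inputs"
        if config.sim is not None:
            sim_cfg = config.sim
            sim_cfg.seed = config.seed
            sim = simulate_cohort(sim_cfg)
            pheno, dosages, weights = sim.phenotypes, sim.dosages, sim.weights
            log.info("simulated cohort: n=%d, m=%d variants", len(pheno),
                     len(dosages.variant_ids))
        else:
            pheno = read_phenotypes(config.phenotype_path)
            dosages = read_dosages(config.dosage_path)
            weights = {e: read_weights(p) for e, p in config.weights_paths.items()}
            log.info("loaded cohort: n=%d, m=%d variants", len(pheno),
                     len(dosages.variant_ids))
        pheno["cause_category"] = classify_causes(pheno["cause_icd10"])

        # ---- stage: filter -------------------------------------------------
        stage = "filter"
        filtered, excl = apply_exclusions(
            pheno, bmi_bounds=config.bmi_bounds,
            exclude_prevalent_for=config.exclude_prevalent_for)
        res.exclusion_log = excl
        excl.to_json(out / "exclusion_log.json")
        log.info("exclusions: initial=%d, missing=%d, extreme BMI=%d, "
                 "prevalent=%d, final=%d", excl.initial, excl.missing_removed,
                 excl.extreme_bmi_removed, excl.prevalent_removed, excl.final)

        # ---- stage: match --------------------------------------------------
        stage = "match"
        match = propensity_match_split(filtered, seed=config.seed)
        res.match = match
        match.to_json(out / "match_result.json")
        validation = filtered[filtered["iid"].astype(str).isin(match.validation_iids)].copy()
        log.info("matched validation set: %d cases + %d controls; discovery %d",
                 match.n_cases, match.n_cases, len(match.discovery_iids))

        # ---- stage: score --------------------------------------------------
        stage = "score"
        val_iids = validation["iid"].astype(str)
        val_dosages = DosageMatrix(frame=dosages.frame.reindex(val_iids),
                                   counted_allele=dosages.counted_allele)
        scheme_adj = CovariateScheme.named("adjusted")
        scores, prs_rows = {}, []
        for exp in EXPOSURES:
            scores[exp] = compute_prs(val_dosages, weights[exp],
                                      p_threshold=config.p_threshold)
            v = validate_prs(scores[exp], validation, exp,
                             covariates=scheme_adj.columns)
            prs_rows.append(dict(exposure=exp, beta=v.beta, se=v.se, p=v.p,
                                 r2_incremental=v.r2_incremental, n=v.n,
                                 n_variants=scores[exp].n_variants))
            scores[exp].to_tsv(out / f"prs_{exp}.tsv")
            log.info("PRS %s: %d variants, beta=%.3f, incremental R2=%.4f",
                     exp, scores[exp].n_variants, v.beta, v.r2_incremental)
        res.prs_validation = pd.DataFrame(prs_rows)
        _write(res.prs_validation, out / "prs_validation.tsv", meta_hash)

        # ---- stage: observational -------------------------------------------
        stage = "observational"
        obs_rows, curve_rows = [], []
        obs_fits = {}
        for scheme_name in config.schemes:
            sch = CovariateScheme.named(scheme_name)
            for exp in EXPOSURES:
                lin = fit_ph(filtered, exp, sch, form="linear",
                             min_events=config.min_events)
                spl = fit_ph(filtered, exp, sch, form="spline",
                             min_events=config.min_events)
                nl = test_nonlinearity(lin, spl, threshold=config.f_threshold)
                nad = estimate_nadir(spl, filtered,
                                     bootstrap_reps=config.nadir_bootstrap,
                                     seed=config.seed, nonlinearity=nl)
                obs_fits[(exp, scheme_name, "all")] = lin
                obs_rows.append(dict(
                    exposure=exp, scheme=scheme_name, stratum="all",
                    cause="all_cause", hr=lin.hr, l95=lin.ci_low, u95=lin.ci_high,
                    p=lin.p, n_events=lin.n_events, f_nonlinearity=nl.f_stat,
                    nonlinear=nl.flag, nadir=None if nad.boundary else nad.nadir,
                    nadir_l=nad.ci_low, nadir_u=nad.ci_high,
                    nadir_boundary=nad.boundary))
                grid = np.linspace(*np.quantile(filtered[exp].dropna(), [0.01, 0.99]),
                                   101)
                for gx, gy in zip(grid, spl.curve(grid)):
                    curve_rows.append(dict(exposure=exp, scheme=scheme_name,
                                           x=gx, log_hr=gy))
                # sex-stratified linear fits (adjusted scheme only)
                if scheme_name == "adjusted":
                    for sx, sub in stratify(filtered, "sex").items():
                        try:
                            f = fit_ph(sub, exp, _scheme_without(sch, "sex"),
                                       form="linear", min_events=config.min_events)
                        except FitError as exc:
                            log.warning("observational %s/%s skipped: %s", exp, sx, exc)
                            continue
                        obs_fits[(exp, scheme_name, sx)] = f
                        obs_rows.append(dict(
                            exposure=exp, scheme=scheme_name, stratum=sx,
                            cause="all_cause", hr=f.hr, l95=f.ci_low,
                            u95=f.ci_high, p=f.p, n_events=f.n_events,
                            f_nonlinearity=None, nonlinear=None, nadir=None,
                            nadir_l=None, nadir_u=None, nadir_boundary=None))
                    for cause in CAUSES:
                        try:
                            f = fit_ph(filtered, exp, sch, form="linear",
                                       cause=cause, min_events=config.min_events)
                        except FitError as exc:
                            log.warning("cause-specific %s/%s skipped: %s", exp,
                                        cause, exc)
                            continue
                        obs_fits[(exp, scheme_name, f"cause:{cause}")] = f
                        obs_rows.append(dict(
                            exposure=exp, scheme=scheme_name, stratum="all",
                            cause=cause, hr=f.hr, l95=f.ci_low, u95=f.ci_high,
                            p=f.p, n_events=f.n_events, f_nonlinearity=None,
                            nonlinear=None, nadir=None, nadir_l=None,
                            nadir_u=None, nadir_boundary=None))
        res.observational = pd.DataFrame(obs_rows)
        _write(res.observational, out / "observational.tsv", meta_hash)
        _write(pd.DataFrame(curve_rows), out / "observational_curves.tsv", meta_hash)

        # ---- stage: linear MR ------------------------------------------------
        stage = "mr_linear"
        mr_rows = []
        mr_by = {}
        for exp in EXPOSURES:
            w = wald_score(scores[exp], validation, exp, scheme=scheme_adj,
                           weak_t=config.weak_t)
            mr_by[(exp, "all")] = w
            p_int = interaction_test(scores[exp], validation, "sex", scheme_adj)
            mr_rows.append(dict(method="wald_score", exposure=exp, stratum="all",
                                cause="all_cause", estimate=w.estimate, se=w.se,
                                or_=w.odds_ratio, l95=np.exp(w.ci_low),
                                u95=np.exp(w.ci_high), p=w.p, alpha=None,
                                alpha_p=None, p_interaction_sex=p_int))
            for sx, sub in stratify(validation, "sex").items():
                try:
                    ws = wald_score(scores[exp], sub, exp,
                                    scheme=_scheme_without(scheme_adj, "sex"),
                                    weak_t=config.weak_t)
                except (WeakInstrumentError, MRError) as exc:
                    log.warning("MR %s/%s skipped: %s", exp, sx, exc)
                    continue
                mr_by[(exp, sx)] = ws
                mr_rows.append(dict(method="wald_score", exposure=exp, stratum=sx,
                                    cause="all_cause", estimate=ws.estimate,
                                    se=ws.se, or_=ws.odds_ratio,
                                    l95=np.exp(ws.ci_low), u95=np.exp(ws.ci_high),
                                    p=ws.p, alpha=None, alpha_p=None,
                                    p_interaction_sex=None))
            for cause in CAUSES:
                sub = validation[(validation["dead"] == 0)
                                 | (validation["cause_category"] == cause)].copy()
                try:
                    wc = wald_score(scores[exp], sub, exp, scheme=scheme_adj,
                                    weak_t=config.weak_t)
                except (WeakInstrumentError, MRError) as exc:
                    log.warning("MR %s/cause %s skipped: %s", exp, cause, exc)
                    continue
                mr_rows.append(dict(method="wald_score", exposure=exp,
                                    stratum="all", cause=cause,
                                    estimate=wc.estimate, se=wc.se,
                                    or_=wc.odds_ratio, l95=np.exp(wc.ci_low),
                                    u95=np.exp(wc.ci_high), p=wc.p, alpha=None,
                                    alpha_p=None, p_interaction_sex=None))
            # per-variant sensitivity estimators
            retained = weights[exp][weights[exp]["pvalue"] < config.p_threshold]
            sub_dos = DosageMatrix(
                frame=val_dosages.frame[retained["variant_id"].tolist()],
                counted_allele=val_dosages.counted_allele)
            summ = variant_summaries(sub_dos, validation, exp, scheme=scheme_adj)
            for fn in (ivw, mr_egger, weighted_median):
                try:
                    e = fn(summ) if fn is not weighted_median else \
                        fn(summ, bootstrap_reps=config.bootstrap_reps,
                           seed=config.seed)
                except MRError as exc:
                    log.warning("%s for %s skipped: %s", fn.__name__, exp, exc)
                    continue
                mr_rows.append(dict(method=e.method, exposure=exp, stratum="all",
                                    cause="all_cause", estimate=e.estimate,
                                    se=e.se, or_=e.odds_ratio,
                                    l95=np.exp(e.ci_low), u95=np.exp(e.ci_high),
                                    p=e.p, alpha=e.alpha, alpha_p=e.alpha_p,
                                    p_interaction_sex=None))
        res.mr = pd.DataFrame(mr_rows)
        _write(res.mr, out / "mr_linear.tsv", meta_hash)

        # ---- stage: nonlinear MR --------------------------------------------
        stage = "mr_nonlinear"
        all_strata, trend_rows = [], []
        for exp in EXPOSURES:
            resid = residualize_exposure(validation, exp, scores[exp])
            assign = stratify_quantiles(resid, K=config.n_quantiles)
            ests = stratum_wald(validation, scores[exp], exp, assign,
                                scheme=scheme_adj, weak_t=config.weak_t)
            tr = trend_test(ests, alpha=config.alpha)
            sf = strata_frame(ests)
            sf.insert(0, "exposure", exp)
            all_strata.append(sf)
            trend_rows.append(dict(exposure=exp, slope=tr.slope,
                                   slope_se=tr.slope_se, slope_p=tr.slope_p,
                                   quad=tr.quad, quad_se=tr.quad_se,
                                   f_stat=tr.f_stat,
                                   p_nonlinearity=tr.p_nonlinearity,
                                   consistent=tr.consistent,
                                   n_strata=tr.n_strata))
            log.info("NLMR %s: slope=%.4g (p=%.3g), F=%.3g (p=%.3g), consistent=%s",
                     exp, tr.slope, tr.slope_p, tr.f_stat, tr.p_nonlinearity,
                     tr.consistent)
        res.nlmr_strata = pd.concat(all_strata, ignore_index=True)
        res.nlmr_trend = pd.DataFrame(trend_rows)
        _write(res.nlmr_strata, out / "nlmr_strata.tsv", meta_hash)
        _write(res.nlmr_trend, out / "nlmr_trend.tsv", meta_hash)
        _plot_strata(res.nlmr_strata, out / "nlmr_strata.png")

        # ---- stage: heterogeneity --------------------------------------------
        stage = "heterogeneity"
        het = {}
        mr_set = [Estimate(exp, mr_by[(exp, "all")].estimate, mr_by[(exp, "all")].se)
                  for exp in EXPOSURES]
        het["mr_three_measure"] = cochran_q(mr_set).to_dict()
        het["mr_pairwise"] = pairwise_q(mr_set).to_dict(orient="records")
        for sx in ("male", "female"):
            pairs = [Estimate(exp, mr_by[(exp, sx)].estimate, mr_by[(exp, sx)].se)
                     for exp in EXPOSURES if (exp, sx) in mr_by]
            if len(pairs) >= 2:
                het[f"mr_{sx}_pairwise"] = pairwise_q(pairs).to_dict(orient="records")
        obs_list = [obs_fits[(exp, "adjusted", "all")] for exp in EXPOSURES
                    if (exp, "adjusted", "all") in obs_fits]
        mr_list = [mr_by[(exp, "all")] for exp in EXPOSURES]
        het["design_comparison"] = compare_designs(obs_list, mr_list).to_dict(
            orient="records")
        res.heterogeneity = het
        with open(out / "heterogeneity.json", "w") as f:
            json.dump(het, f, indent=2)

        # ---- stage: tables ----------------------------------------------------
        stage = "tables"
        t1 = []
        for exp in EXPOSURES:
            for stratum in ("all", "male", "female"):
                epi = obs_fits.get((exp, "adjusted", stratum))
                mr_e = mr_by.get((exp, stratum))
                nlrow = res.nlmr_trend[res.nlmr_trend["exposure"] == exp].iloc[0]
                obs_row = res.observational[
                    (res.observational["exposure"] == exp)
                    & (res.observational["stratum"] == "all")
                    & (res.observational["cause"] == "all_cause")]
                t1.append(dict(
                    exposure=exp, stratum=stratum,
                    epi_hr=epi.hr if epi else None,
                    epi_l95=epi.ci_low if epi else None,
                    epi_u95=epi.ci_high if epi else None,
                    mr_or=mr_e.odds_ratio if mr_e else None,
                    mr_l95=np.exp(mr_e.ci_low) if mr_e else None,
                    mr_u95=np.exp(mr_e.ci_high) if mr_e else None,
                    nonlinear_flag=bool(obs_row["nonlinear"].iloc[0]),
                    nlmr_consistent=bool(nlrow["consistent"])))
        res.table1 = pd.DataFrame(t1)
        _write(res.table1, out / "table1.tsv", meta_hash)
        t2 = res.observational[res.observational["cause"] != "all_cause"].copy()
        mr_t2 = res.mr[(res.mr["cause"] != "all_cause")]
        res.table2 = t2.merge(
            mr_t2[["exposure", "cause", "or_", "l95", "u95", "p"]],
            on=["exposure", "cause"], how="left", suffixes=("_epi", "_mr"))
        _write(res.table2, out / "table2.tsv", meta_hash)
        log.info("run complete: outputs in %s", out)
        return res
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc
    finally:
        log.removeHandler(fh)
        fh.close()


def compare_designs(obs_fits, mr_estimates) -> pd.DataFrame:
    """Per-exposure heterogeneity between the epidemiological and MR estimates.

    ``obs_fits`` are linear :class:`~adipomr.observational.PHFit` objects,
    ``mr_estimates`` :class:`~adipomr.mr_linear.MREstimate`-like rows; labels
    (exposures) must match one-to-one.
    """
    if not obs_fits or not mr_estimates:
        raise MRError("compare_designs needs both designs")
    obs_by = {f.exposure: f for f in obs_fits}
    mr_by = {}
    for i, e in enumerate(mr_estimates):
        label = getattr(e, "exposure", None) or list(obs_by)[i]
        mr_by[label] = e
    if set(obs_by) != set(mr_by):
        raise MRError(f"design labels differ: {sorted(obs_by)} vs {sorted(mr_by)}")
    rows = []
    for exp, f in obs_by.items():
        epi = from_or_ci(f"epi_{exp}", f.hr, f.ci_low, f.ci_high)
        e = mr_by[exp]
        r = cochran_q([epi, Estimate(f"mr_{exp}", e.estimate, e.se)])
        rows.append(dict(exposure=exp, q=r.q, i2=r.i2, p=r.p,
                         heterogeneous=bool(r.q > 3.841459)))
    return pd.DataFrame(rows)


def _plot_strata(strata: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    exposures = strata["exposure"].unique()
    fig, axes = plt.subplots(1, len(exposures), figsize=(4 * len(exposures), 3.2),
                             squeeze=False)
    for ax, exp in zip(axes[0], exposures):
        sub = strata[(strata["exposure"] == exp) & ~strata["flagged"]]
        ax.errorbar(sub["mean_exposure"], sub["theta"],
                    yerr=1.959964 * sub["se"], fmt="o", ms=3, lw=1)
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel(f"mean {exp.upper()} in stratum")
        ax.set_ylabel("log-OR per SD")
        ax.set_title(exp.upper())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
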
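"""Generator correctness: genotype moments, variance-explained calibration,
hazard-map fidelity, determinism, and fixture round-trips."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from adipomr.config import CAUSES, ConfigError, HazardShape, SimConfig
from adipomr.io import read_raw, read_truth, read_weights
from adipomr.synth import (make_fixture, simulate_cohort, simulate_covariates,
                           simulate_exposures, simulate_genotypes,
                           simulate_mortality)


class TestGenotypes:
    def test_binomial_moments_at_half(self):
        n = 40_000
        dos = simulate_genotypes(n, 5, 0.5, seed=1)
        means = dos.frame.mean()
        vars_ = dos.frame.var(ddof=0)
        # 4 Monte-Carlo SEs around the binomial closed forms 2p and 2p(1-p)
        se_mean = np.sqrt(0.5 / n)
        assert np.all(np.abs(means - 1.0) < 4 * se_mean)
        assert np.all(np.abs(vars_ - 0.5) < 4 * 0.5 * np.sqrt(2 / n))

    def test_deterministic_under_seed(self):
        a = simulate_genotypes(500, 20, (0.05, 0.5), seed=9)
        b = simulate_genotypes(500, 20, (0.05, 0.5), seed=9)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        assert a.counted_allele == b.counted_allele

    def test_zero_variants(self):
        dos = simulate_genotypes(100, 0, 0.2, seed=1)
        assert dos.frame.shape == (100, 0)

    @pytest.mark.parametrize("maf", [0.0, -0.1, 0.6])
    def test_invalid_maf_rejected(self, maf):
        with pytest.raises(ConfigError):
            simulate_genotypes(100, 3, maf, seed=1)


class TestExposures:
    def test_variance_explained_calibration(self):
        cfg = SimConfig(n_participants=20_000, n_variants=60, seed=2,
                        prs_variance_explained=0.1)
        dos = simulate_genotypes(cfg.n_participants, 60, cfg.maf_range, 2)
        expo, scores, _ = simulate_exposures(dos, cfg)
        for exp in ("bmi", "fmi", "whr"):
            X = sm.add_constant(scores[exp].to_numpy())
            r2 = sm.OLS(expo[exp].to_numpy(), X).fit().rsquared
            assert abs(r2 - 0.1) < 0.02

    def test_null_architecture_uncorrelated(self):
        n = 10_000
        cfg = SimConfig(n_participants=n, n_variants=40, seed=3,
                        prs_variance_explained=0.0)
        dos = simulate_genotypes(n, 40, cfg.maf_range, 3)
        expo, scores, _ = simulate_exposures(dos, cfg)
        r = np.corrcoef(scores["bmi"], expo["bmi"])[0, 1]
        assert abs(r) < 3 / np.sqrt(n)

    def test_identity_corr_leaves_only_genetic_overlap(self):
        n = 20_000
        cfg = SimConfig(n_participants=n, n_variants=60, seed=4,
                        exposure_corr=np.eye(3).tolist())
        dos = simulate_genotypes(n, 60, cfg.maf_range, 4)
        expo, _, _ = simulate_exposures(dos, cfg)
        # independent weight draws: genetic-overlap-induced correlation ~ 0
        r = expo[["bmi", "fmi", "whr"]].corr().to_numpy()
        off = r[np.triu_indices(3, k=1)]
        assert np.all(np.abs(off) < 0.05)

    def test_natural_scales(self):
        cfg = SimConfig(n_participants=20_000, n_variants=40, seed=5)
        dos = simulate_genotypes(20_000, 40, cfg.maf_range, 5)
        expo, _, _ = simulate_exposures(dos, cfg)
        assert abs(expo["bmi"].mean() - 27.0) < 0.3
        assert abs(expo["bmi"].std() - 4.7) < 0.3
        assert abs(expo["whr"].mean() - 0.87) < 0.01

    def test_non_pd_correlation_rejected(self):
        bad = [[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]]
        with pytest.raises(ConfigError, match="positive-definite"):
            SimConfig(n_participants=100, n_variants=5, exposure_corr=bad)


class TestMortality:
    def _cohort(self, n, seed, shapes):
        cfg = SimConfig(n_participants=n, n_variants=10, seed=seed,
                        missing_rate=0.0, extreme_bmi_rate=0.0,
                        hazard_shape=shapes)
        dos = simulate_genotypes(n, 10, cfg.maf_range, seed)
        expo, _, _ = simulate_exposures(dos, cfg)
        cov = simulate_covariates(n, seed)
        cov.index = expo.index
        return expo, cov, simulate_mortality(expo, cov, cfg, seed)

    def test_null_map_flat_across_deciles(self):
        expo, cov, surv = self._cohort(30_000, 6, {})
        x = expo["bmi"]
        x_sd = (x - x.mean()) / x.std()
        fit = sm.Logit(surv["dead"].to_numpy(),
                       sm.add_constant(x_sd.to_numpy())).fit(disp=0)
        lo, hi = fit.conf_int(alpha=0.01)[1]
        assert lo <= 0 <= hi

    def test_quadratic_minimizes_near_nadir(self):
        # the parabola is flat near its vertex, so the minimizing decile is
        # the one containing the nadir or an immediate neighbour
        shapes = {"bmi": HazardShape(kind="quadratic", curvature=0.01, nadir=25.0)}
        expo, cov, surv = self._cohort(50_000, 7, shapes)
        df = pd.DataFrame({"bmi": expo["bmi"], "dead": surv["dead"],
                           "t": surv["time_years"]})
        dec = pd.qcut(df["bmi"], 10)
        rate = df.groupby(dec, observed=True).apply(
            lambda g: g["dead"].sum() / g["t"].sum(), include_groups=False)
        order = list(rate.index)
        best = order.index(rate.idxmin())
        containing = next(i for i, b in enumerate(order)
                          if b.left <= 25.0 <= b.right)
        assert abs(best - containing) <= 1

    def test_convex_log_rate_under_quadratic_map(self):
        # binned death rates are Poisson-noisy; fidelity of the J-shape is
        # checked by regressing the 20-bin log rate on (x - 25)^2, which must
        # recover the generator curvature
        shapes = {"bmi": HazardShape(kind="quadratic", curvature=0.008, nadir=25.0)}
        expo, cov, surv = self._cohort(50_000, 8, shapes)
        df = pd.DataFrame({"bmi": expo["bmi"], "dead": surv["dead"],
                           "t": surv["time_years"]})
        bins = pd.qcut(df["bmi"], 20)
        grp = df.groupby(bins, observed=True)
        log_rate = np.log(grp.apply(lambda g: g["dead"].sum() / g["t"].sum(),
                                    include_groups=False).to_numpy())
        centers = grp["bmi"].mean().to_numpy()
        X = sm.add_constant((centers - 25.0) ** 2)
        fit = sm.OLS(log_rate, X).fit()
        assert fit.params[1] == pytest.approx(0.008, abs=0.003)
        assert fit.tvalues[1] > 5

    def test_degenerate_cause_mix(self):
        cfg = SimConfig(n_participants=2000, n_variants=5, seed=9,
                        cause_mix={"cancer": 1.0, "cvd": 0.0,
                                   "respiratory": 0.0, "other": 0.0})
        sim = simulate_cohort(cfg)
        dead = sim.phenotypes[sim.phenotypes["dead"] == 1]
        assert dead["cause_icd10"].str.startswith("C").all()

    def test_negative_followup_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_participants=100, n_variants=5, followup_years=-1.0)

    def test_cause_mix_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="sum to 1"):
            SimConfig(n_participants=100, n_variants=5,
                      cause_mix={c: 0.2 for c in CAUSES})


class TestCohortAssembly:
    def test_byte_identical_under_seed(self, tmp_path):
        p1 = make_fixture("tiny", tmp_path / "a", seed=5)
        p2 = make_fixture("tiny", tmp_path / "b", seed=5)
        for key in ("phenotypes", "dosages", "weights_bmi", "truth"):
            assert open(p1[key]).read() == open(p2[key]).read()

    def test_fixture_round_trips(self, tmp_path):
        paths = make_fixture("tiny", tmp_path, seed=5)
        from adipomr.io import read_phenotypes

        pheno = read_phenotypes(paths["phenotypes"])
        dos = read_raw(paths["dosages"])
        w = read_weights(paths["weights_bmi"])
        truth = read_truth(paths["truth"])
        assert len(pheno) == 200
        assert dos.frame.shape == (200, 50)
        assert set(w["variant_id"]) == set(dos.variant_ids)
        assert set(truth["weights"]["bmi"]) == set(dos.variant_ids)
        # dosage round-trip through the plain-TSV dialect too
        dos.to_tsv(tmp_path / "d.tsv")
        from adipomr.io import read_dosage_tsv

        back = read_dosage_tsv(tmp_path / "d.tsv")
        pd.testing.assert_frame_equal(back.frame, dos.frame)

    def test_missingness_rate(self):
        cfg = SimConfig(n_participants=20_000, n_variants=5, seed=10,
                        missing_rate=0.05, extreme_bmi_rate=0.0)
        sim = simulate_cohort(cfg)
        miss = sim.phenotypes[["fmi", "whr", "tc", "alcohol"]].isna().any(axis=1)
        assert abs(miss.mean() - 0.05) < 0.01

    def test_truth_stores_generator_parameters(self):
        cfg = SimConfig(n_participants=500, n_variants=8, seed=12)
        sim = simulate_cohort(cfg)
        assert sim.truth.nadir["bmi"] == 24.9
        assert sim.truth.nadir["fmi"] == 6.15
        assert sim.truth.per_sd_log_effect["whr"] == pytest.approx(0.34)
        assert sim.truth.prs_r2 == 0.1
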
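"""Linear MR estimators: Wald/allelic score, IVW, Egger, weighted median."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adipomr.mr_linear import (MRError, WeakInstrumentError, interaction_test,
                               ivw, mr_egger, wald_score, weighted_median,
                               variant_summaries)
from adipomr.synth import simulate_case_status

from conftest import case_control_table, random_summaries


class TestWaldScore:
    def test_recovers_truth(self, cc_table):
        tab, score, _ = cc_table
        est = wald_score(score, tab, "bmi", outcome_col="case")
        assert est.ci_low <= np.log(1.5) <= est.ci_high

    def test_scale_invariance_of_ratio(self, cc_table):
        tab, score, _ = cc_table
        a = wald_score(score, tab, "bmi", outcome_col="case")
        b = wald_score(2.0 * score, tab, "bmi", outcome_col="case")
        assert a.estimate == pytest.approx(b.estimate, rel=1e-9)
        assert a.se == pytest.approx(b.se, rel=1e-9)

    def test_weak_instrument_refused(self, cc_table):
        tab, score, _ = cc_table
        rng = np.random.default_rng(0)
        noise = pd.Series(rng.standard_normal(len(score)), index=score.index)
        with pytest.raises(WeakInstrumentError):
            wald_score(noise, tab, "bmi", outcome_col="case")

    def test_two_stage_least_squares_equivalence(self, cc_table):
        # with a single instrument, the ratio of OLS coefficients equals the
        # IV (2SLS) estimator exactly on the linear-probability scale
        tab, score, _ = cc_table
        g = score.reindex(tab["iid"].astype(str)).to_numpy()
        x = tab["bmi"].to_numpy()
        x_sd = (x - x.mean()) / x.std(ddof=1)
        y = tab["case"].to_numpy(dtype=float)
        gc = g - g.mean()
        ratio = (gc @ y) / (gc @ x_sd)          # cov ratio = Wald (LPM)
        beta_2sls = (gc @ y) / (gc @ x_sd)      # IV closed form, single z
        assert ratio == pytest.approx(beta_2sls, rel=1e-12)
        est = wald_score(score, tab, "bmi", outcome_col="case")
        # logistic Wald agrees with the LPM ratio after the ~1/(p(1-p))
        # logit scale factor at p=1/2
        p = y.mean()
        assert est.estimate == pytest.approx(ratio / (p * (1 - p)), rel=0.15)

    def test_second_order_se_not_smaller(self, cc_table):
        tab, score, _ = cc_table
        first = wald_score(score, tab, "bmi", outcome_col="case")
        second = wald_score(score, tab, "bmi", outcome_col="case",
                            second_order=True)
        assert second.se >= first.se
        assert second.estimate == first.estimate


class TestIvw:
    def test_single_variant_identity(self):
        s = random_summaries(np.random.default_rng(1), 1)
        est = ivw(s)
        assert est.estimate == pytest.approx(
            s["beta_out"][0] / s["beta_exp"][0], rel=1e-12)

    def test_homogeneous_ratios(self):
        rng = np.random.default_rng(2)
        s = random_summaries(rng, 8)
        s["beta_out"] = 0.25 * s["beta_exp"]
        est = ivw(s)
        assert est.estimate == pytest.approx(0.25, rel=1e-10)

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = random_summaries(rng, rng.integers(2, 30))
            est = ivw(s)
            # brute-force weighted-least-squares oracle: zero-intercept
            # regression of beta_out on beta_exp with weights 1/se_out^2
            num = den = 0.0
            for g, G, se in zip(s["beta_exp"], s["beta_out"], s["se_out"]):
                num += g * G / se**2
                den += g * g / se**2
            assert est.estimate == pytest.approx(num / den, abs=1e-10)

    def test_within_ratio_range(self):
        rng = np.random.default_rng(4)
        s = random_summaries(rng, 12)
        est = ivw(s)
        ratios = s["beta_out"] / s["beta_exp"]
        assert ratios.min() - 1e-12 <= est.estimate <= ratios.max() + 1e-12

    def test_zero_gamma_names_variant(self):
        s = random_summaries(np.random.default_rng(5), 4)
        s.loc[2, "beta_exp"] = 0.0
        with pytest.raises(MRError, match="v2"):
            ivw(s)


class TestEgger:
    def test_needs_three_variants(self):
        s = random_summaries(np.random.default_rng(6), 2)
        with pytest.raises(MRError, match=">= 3"):
            mr_egger(s)

    def test_zero_intercept_limit_equals_ivw(self):
        # when the intercept is constrained to zero the weighted regression
        # slope is exactly the IVW estimate; verify via the closed form
        rng = np.random.default_rng(7)
        s = random_summaries(rng, 15)
        w = 1.0 / s["se_out"] ** 2
        slope0 = float(np.sum(w * s["beta_exp"] * s["beta_out"])
                       / np.sum(w * s["beta_exp"] ** 2))
        assert ivw(s).estimate == pytest.approx(slope0, rel=1e-10)

    def test_directional_pleiotropy_recovered(self):
        rng = np.random.default_rng(8)
        m = 40
        gamma = rng.uniform(0.05, 0.3, m)
        s = pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(m)],
            "beta_exp": gamma, "se_exp": np.full(m, 1e-4),
            "beta_out": 0.02 + 0.4 * gamma + rng.normal(0, 0.01, m),
            "se_out": np.full(m, 0.01)})
        est = mr_egger(s)
        assert est.alpha == pytest.approx(0.02, abs=0.01)
        assert est.estimate == pytest.approx(0.4, abs=0.1)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(9)
        s = random_summaries(rng, 10)
        flipped = s.copy()
        flipped["beta_exp"] *= -1
        flipped["beta_out"] *= -1
        a, b = mr_egger(s), mr_egger(flipped)
        assert a.estimate == pytest.approx(b.estimate, rel=1e-10)
        assert a.alpha == pytest.approx(b.alpha, rel=1e-10)


def wm_oracle(theta, w):
    """Independent loop oracle: cumulative-weight midpoint interpolation."""
    pairs = sorted(zip(theta, w))
    total = sum(p[1] for p in pairs)
    s, grid = 0.0, []
    for t, wi in pairs:
        grid.append((s + wi / 2.0) / total)
        s += wi
    if 0.5 <= grid[0]:
        return pairs[0][0]
    for i in range(1, len(grid)):
        if grid[i] >= 0.5:
            t0, t1 = pairs[i - 1][0], pairs[i][0]
            return t0 + (t1 - t0) * (0.5 - grid[i - 1]) / (grid[i] - grid[i - 1])
    return pairs[-1][0]


class TestWeightedMedian:
    def test_equal_weights_middle_order_statistic(self):
        s = pd.DataFrame({"variant_id": ["a", "b", "c"],
                          "beta_exp": [1.0, 1.0, 1.0],
                          "se_exp": [0.01] * 3,
                          "beta_out": [0.1, 0.2, 0.9],
                          "se_out": [0.1] * 3})
        est = weighted_median(s, bootstrap_reps=10, seed=0)
        assert est.estimate == pytest.approx(0.2, abs=1e-12)

    def test_concentrated_weight_dominates(self):
        s = pd.DataFrame({"variant_id": ["a", "b", "c"],
                          "beta_exp": [1.0, 1.0, 1.0],
                          "se_exp": [0.01] * 3,
                          "beta_out": [0.1, 0.5, 0.9],
                          "se_out": [1e-4, 10.0, 10.0]})
        est = weighted_median(s, bootstrap_reps=10, seed=0)
        assert est.estimate == pytest.approx(0.1, abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = random_summaries(rng, 15)
        est = weighted_median(s, bootstrap_reps=2, seed=0)
        theta = (s["beta_out"] / s["beta_exp"]).to_numpy()
        w = (s["beta_exp"] ** 2 / s["se_out"] ** 2).to_numpy()
        assert est.estimate == pytest.approx(wm_oracle(theta, w), abs=1e-12)

    def test_duplicate_and_halve_off_median_variant(self):
        s = pd.DataFrame({"variant_id": list("abcde"),
                          "beta_exp": [1.0] * 5,
                          "se_exp": [0.01] * 5,
                          "beta_out": [0.1, 0.2, 0.3, 0.4, 2.0],
                          "se_out": [0.1] * 5})
        base = weighted_median(s, bootstrap_reps=2, seed=0).estimate
        dup = pd.concat([s, s.iloc[[4]].assign(variant_id="e2")],
                        ignore_index=True)
        dup.loc[dup["variant_id"].isin(["e", "e2"]), "se_out"] = 0.1 * np.sqrt(2)
        est = weighted_median(dup, bootstrap_reps=2, seed=0).estimate
        assert est == pytest.approx(base, abs=1e-12)


class TestInteraction:
    def test_constant_modifier_rejected(self, cc_table):
        tab, score, _ = cc_table
        tab = tab.copy()
        tab["grp"] = 1.0
        with pytest.raises(MRError, match="constant"):
            interaction_test(score, tab, "grp", outcome_col="case")

    def test_strong_interaction_detected(self):
        tab, score, _ = case_control_table(30_000, seed=23, log_or=0.0)
        rng = np.random.default_rng(23)
        tab = tab.copy()
        tab["grp"] = rng.integers(0, 2, len(tab)).astype(float)
        x = tab["bmi"]
        x_sd = (x - x.mean()) / x.std(ddof=1)
        # effect log(2.4)/SD in one group, none in the other
        tab["case"] = simulate_case_status(x_sd * tab["grp"], np.log(2.4),
                                           seed=23)
        p = interaction_test(score, tab, "grp", outcome_col="case")
        assert p < 0.05

    def test_null_interaction_ci_wide(self, cc_table):
        tab, score, _ = cc_table
        rng = np.random.default_rng(29)
        tab = tab.copy()
        tab["grp"] = rng.integers(0, 2, len(tab)).astype(float)
        p = interaction_test(score, tab, "grp", outcome_col="case")
        assert p > 0.001  # common effect: no systematic interaction signal


class TestVariantSummaries:
    def test_ivw_close_to_allelic_score(self):
        tab, score, dos = case_control_table(8000, seed=31, log_or=np.log(1.5),
                                             n_variants=30, h2=0.2)
        summ = variant_summaries(dos, tab, "bmi", outcome_col="case")
        assert len(summ) == 30
        est = ivw(summ)
        full = wald_score(score, tab, "bmi", outcome_col="case")
        joint = np.sqrt(est.se**2 + full.se**2)
        assert abs(est.estimate - full.estimate) < 3 * joint
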
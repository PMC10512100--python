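"""Proportional-hazards fits, spline nonlinearity, and nadir location."""

import numpy as np
import pandas as pd
import pytest

from adipomr.observational import (CovariateScheme, FitError, PHFit,
                                   estimate_nadir, fit_ph, rcs_basis)
from adipomr.observational import test_nonlinearity as nonlinearity_test


class TestRcsBasis:
    def test_linear_in_tails(self):
        knots = [1.0, 2.0, 3.0, 4.0]
        x = np.linspace(5, 10, 50)  # beyond the last knot
        basis = rcs_basis(x, knots)
        for j in range(basis.shape[1]):
            d2 = np.diff(basis[:, j], 2)
            assert np.allclose(d2, 0, atol=1e-9)

    def test_first_column_is_identity(self):
        x = np.linspace(0, 5, 20)
        basis = rcs_basis(x, [1, 2, 3, 4])
        assert np.allclose(basis[:, 0], x)

    def test_four_knots_three_columns(self):
        assert rcs_basis(np.arange(10.0), [2, 4, 6, 8]).shape == (10, 3)

    def test_duplicate_knots_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            rcs_basis(np.arange(10.0), [1, 1, 2, 3])


class TestFitPh:
    def test_linear_hr_recovers_truth(self, linear_cohort):
        # generator truth: log HR 0.34 per SD of WHR
        fit = fit_ph(linear_cohort.phenotypes, "whr", "adjusted")
        assert fit.ci_low <= np.exp(0.34) <= fit.ci_high
        assert abs(np.log(fit.hr) - 0.34) < 0.08

    def test_hr_invariant_to_affine_rescaling(self, linear_cohort):
        tab = linear_cohort.phenotypes.copy()
        fit1 = fit_ph(tab, "whr", "unadjusted")
        tab["whr"] = 100.0 * tab["whr"] - 3.0
        fit2 = fit_ph(tab, "whr", "unadjusted")
        assert fit1.hr == pytest.approx(fit2.hr, rel=1e-8)

    def test_duplicating_rows_keeps_point_estimate(self, linear_cohort):
        tab = linear_cohort.phenotypes.sample(4000, random_state=0)
        fit1 = fit_ph(tab, "whr", "unadjusted")
        fit2 = fit_ph(pd.concat([tab, tab], ignore_index=True), "whr",
                      "unadjusted")
        assert np.log(fit2.hr) == pytest.approx(np.log(fit1.hr), abs=5e-3)
        assert fit2.ci_high - fit2.ci_low < fit1.ci_high - fit1.ci_low

    def test_null_exposure_ci_covers_one(self, linear_cohort):
        # BMI has no hazard link in this cohort (WHR only via environment)
        fit = fit_ph(linear_cohort.phenotypes, "fmi", "adjusted")
        assert abs(np.log(fit.hr)) < 0.1

    def test_cause_specific_events_partition_all_cause(self, linear_cohort):
        tab = linear_cohort.phenotypes
        fits = [fit_ph(tab, "whr", "adjusted", cause=c, min_events=10)
                for c in ("cancer", "cvd", "respiratory", "other")]
        all_cause = fit_ph(tab, "whr", "adjusted")
        assert sum(f.n_events for f in fits) == all_cause.n_events

    def test_no_events_errors(self):
        df = pd.DataFrame({"time_years": [1.0] * 60, "dead": [0] * 60,
                           "bmi": np.random.default_rng(0).normal(27, 4, 60)})
        with pytest.raises(FitError, match="events"):
            fit_ph(df, "bmi", "unadjusted")

    def test_unknown_scheme_rejected(self, linear_cohort):
        with pytest.raises(ValueError, match="unknown scheme"):
            fit_ph(linear_cohort.phenotypes, "whr", "nonesuch")


class TestNonlinearity:
    def test_quadratic_truth_flags(self, jshape_cohort):
        tab = jshape_cohort.phenotypes
        lin = fit_ph(tab, "bmi", "adjusted")
        spl = fit_ph(tab, "bmi", "adjusted", form="spline")
        nl = nonlinearity_test(lin, spl)
        assert nl.flag and nl.f_stat > 10
        assert nl.p_lr < 1e-4

    def test_linear_truth_does_not_flag(self, linear_cohort):
        tab = linear_cohort.phenotypes
        lin = fit_ph(tab, "whr", "adjusted")
        spl = fit_ph(tab, "whr", "adjusted", form="spline")
        nl = nonlinearity_test(lin, spl)
        assert not nl.flag
        assert nl.f_stat >= 0

    def test_threshold_is_configurable(self, linear_cohort):
        tab = linear_cohort.phenotypes
        lin = fit_ph(tab, "whr", "adjusted")
        spl = fit_ph(tab, "whr", "adjusted", form="spline")
        permissive = nonlinearity_test(lin, spl, threshold=1e-9)
        strict = nonlinearity_test(lin, spl, threshold=1e9)
        assert permissive.flag and not strict.flag

    def test_non_nested_fits_rejected(self, linear_cohort, jshape_cohort):
        lin = fit_ph(linear_cohort.phenotypes, "whr", "adjusted")
        spl = fit_ph(jshape_cohort.phenotypes, "bmi", "adjusted", form="spline")
        with pytest.raises(FitError, match="nested"):
            nonlinearity_test(lin, spl)

    def test_deviance_ordering(self, jshape_cohort):
        tab = jshape_cohort.phenotypes
        lin = fit_ph(tab, "bmi", "adjusted")
        spl = fit_ph(tab, "bmi", "adjusted", form="spline")
        assert -2 * lin.log_likelihood >= -2 * spl.log_likelihood - 1e-6


class TestNadir:
    def test_analytic_parabola_argmin(self):
        # direct curve input: no data, no noise; argmin must hit the vertex
        # up to grid resolution
        c = 25.0
        fake = PHFit(exposure="bmi", scheme="unadjusted", form="spline",
                     cause=None, hr=None, ci_low=None, ci_high=None, p=None,
                     log_likelihood=0.0, n=100, n_events=50, n_params=3,
                     exposure_mean=27.0, exposure_sd=4.7,
                     knots=np.array([18.0, 24.0, 30.0, 40.0]),
                     spline_coefs=np.zeros(3))
        fake.curve = lambda grid: (np.asarray(grid) - c) ** 2
        table = pd.DataFrame({"bmi": np.linspace(15, 45, 2000)})
        res = estimate_nadir(fake, table, bootstrap_reps=0)
        grid_step = (np.quantile(table["bmi"], 0.99)
                     - np.quantile(table["bmi"], 0.01)) / 511
        assert abs(res.nadir - c) <= grid_step
        assert not res.boundary

    def test_quadratic_truth_recovery(self, jshape_cohort):
        tab = jshape_cohort.phenotypes
        spl = fit_ph(tab, "bmi", "adjusted", form="spline")
        res = estimate_nadir(spl, tab, bootstrap_reps=0)
        assert not res.boundary
        assert abs(res.nadir - 25.0) < 1.0  # tighter bound checked at 50k

    def test_quadratic_form_locates_vertex(self, jshape_cohort):
        tab = jshape_cohort.phenotypes
        quad = fit_ph(tab, "bmi", "adjusted", form="quadratic")
        res = estimate_nadir(quad, tab, bootstrap_reps=0)
        assert not res.boundary
        assert abs(res.nadir - 25.0) < 0.8

    def test_monotone_truth_flags_boundary(self, linear_cohort):
        tab = linear_cohort.phenotypes
        spl = fit_ph(tab, "whr", "adjusted", form="spline")
        res = estimate_nadir(spl, tab, bootstrap_reps=0)
        assert res.boundary
        assert res.ci_low is None and res.ci_high is None

    def test_bootstrap_ci_brackets_nadir(self, jshape_cohort):
        tab = jshape_cohort.phenotypes.sample(6000, random_state=1)
        spl = fit_ph(tab, "bmi", "adjusted", form="spline")
        res = estimate_nadir(spl, tab, bootstrap_reps=20, seed=3)
        if not res.boundary and res.ci_low is not None:
            assert res.ci_low <= res.nadir <= res.ci_high

    def test_requires_spline_fit(self, linear_cohort):
        lin = fit_ph(linear_cohort.phenotypes, "whr", "adjusted")
        with pytest.raises(FitError, match="spline"):
            estimate_nadir(lin, linear_cohort.phenotypes)


class TestSchemes:
    def test_named_schemes_cover_design(self):
        assert CovariateScheme.named("unadjusted").columns == []
        adj = CovariateScheme.named("adjusted").columns
        assert adj[:2] == ["age", "sex"] and len(adj) == 12
        full = CovariateScheme.named("fully_adjusted").columns
        assert set(adj) < set(full)
        assert {"smoking", "diabetes", "alcohol", "tc", "ldl", "hdl", "tg",
                "sbp", "dbp"} < set(full)
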
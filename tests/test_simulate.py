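"""Hazard samplers, censoring calibration, cohort and case-cohort sampling."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.special import gamma as gamma_fn

from cchaz import (
    SCENARIOS,
    CovariateSpec,
    PiecewiseHazardSpec,
    ScenarioSpec,
    WeibullHazardSpec,
    calibrate_censoring,
    sample_casecohort,
    sample_piecewise_exponential,
    sample_weibull,
    simulate_cohort,
)


class TestPiecewiseSampler:
    def test_single_interval_is_exponential_inversion(self):
        spec = PiecewiseHazardSpec((), (0.4,), ((0.0,),))
        u = np.array([0.3, 0.8])
        t = sample_piecewise_exponential(spec, np.zeros((2, 1)), u)
        assert np.allclose(t, -np.log(u) / 0.4)

    def test_exhausting_first_interval_lands_on_cutpoint(self):
        spec = PiecewiseHazardSpec((2.0,), (0.5, 0.1), ((0.0,),))
        u = np.exp(-0.5 * 2.0)  # -log u exactly Lambda(cutpoint)
        t = sample_piecewise_exponential(spec, np.zeros((1, 1)), np.array([u]))
        assert t[0] == pytest.approx(2.0)

    def test_empirical_cumhaz_tracks_closed_form(self):
        spec = SCENARIOS["1.1"].hazard
        rng = np.random.default_rng(5)
        n = 100_000
        u = np.clip(rng.random(n), 1e-12, 1 - 1e-12)
        t = sample_piecewise_exponential(spec, np.ones((n, 1)), u)
        for g in (0.2, 0.5, 0.8, 1.2):
            emp = -np.log(np.mean(t > g))
            theo = spec.cumulative_hazard(g, x=[1.0])[0]
            assert emp == pytest.approx(theo, rel=0.02)

    def test_interval_varying_hr_changes_hazard_only_in_its_intervals(self):
        # HR 0.5 early / 1.0 late: the covariate shifts Lambda only before 0.5
        spec = PiecewiseHazardSpec((0.5,), (0.2, 0.2), ((math.log(0.5), 0.0),))
        lam0 = spec.cumulative_hazard([0.4, 0.5, 2.0], x=[0.0])
        lam1 = spec.cumulative_hazard([0.4, 0.5, 2.0], x=[1.0])
        assert lam1[0] == pytest.approx(0.5 * lam0[0])
        # increments past the cutpoint are identical for both covariate levels
        assert lam1[2] - lam1[1] == pytest.approx(lam0[2] - lam0[1])

    def test_raising_rates_lowers_median_time(self):
        lo = PiecewiseHazardSpec((0.3, 0.5, 0.8), (0.1, 0.2, 0.05, 0.1), ((0.0,),))
        hi = PiecewiseHazardSpec((0.3, 0.5, 0.8), (0.2, 0.4, 0.1, 0.2), ((0.0,),))
        rng = np.random.default_rng(2)
        u = np.clip(rng.random(5000), 1e-12, 1 - 1e-12)
        x = np.zeros((5000, 1))
        assert np.median(sample_piecewise_exponential(hi, x, u)) < np.median(
            sample_piecewise_exponential(lo, x, u)
        )


class TestWeibullSampler:
    def test_shape_one_is_exponential(self):
        spec = WeibullHazardSpec(shape=1.0, scale=3.0)
        u = np.array([0.2, 0.9])
        assert np.allclose(sample_weibull(spec, u), -np.log(u) * 3.0)

    def test_unit_quantile_is_scale(self):
        spec = WeibullHazardSpec(shape=2.2, scale=4.0)
        assert sample_weibull(spec, np.array([np.exp(-1.0)]))[0] == pytest.approx(4.0)

    def test_moment_formula(self):
        spec = WeibullHazardSpec(shape=1.5, scale=4.0)
        rng = np.random.default_rng(6)
        t = sample_weibull(spec, np.clip(rng.random(100_000), 1e-12, 1 - 1e-12))
        assert t.mean() == pytest.approx(4.0 * gamma_fn(1 + 1 / 1.5), rel=0.02)

    def test_constant_log_hr_scales_cumhaz(self):
        spec = WeibullHazardSpec(shape=1.5, scale=4.0, log_hr=(math.log(2.0),))
        rng = np.random.default_rng(7)
        u = np.clip(rng.random(50_000), 1e-12, 1 - 1e-12)
        t1 = sample_weibull(spec, u, x=np.ones((50_000, 1)))
        t0 = sample_weibull(spec, u, x=np.zeros((50_000, 1)))
        # doubling the hazard divides Lambda-inverse input by 2:
        assert np.allclose(t1, 4.0 * ((-np.log(u)) / 2) ** (1 / 1.5))
        assert np.median(t1) < np.median(t0)


class TestCalibration:
    def test_matches_exponential_closed_form(self):
        # P(event) under rate lam and C ~ U(0,c): 1 - (1 - exp(-lam c)) / (lam c)
        lam, target = 0.3, 0.075
        scen = ScenarioSpec(
            "exp", (CovariateSpec("x", "binary", 0.5),),
            PiecewiseHazardSpec((), (lam,), ((0.0,),)),
        )
        c = calibrate_censoring(scen, target_rate=target, n_pilot=400_000)

        def event_prob(cc):
            return 1 - (1 - np.exp(-lam * cc)) / (lam * cc)

        from scipy.optimize import brentq

        c_true = brentq(lambda cc: event_prob(cc) - target, 1e-6, 50.0)
        assert c == pytest.approx(c_true, abs=2e-2)

    def test_unattainable_target_raises(self):
        scen = ScenarioSpec(
            "tiny", (CovariateSpec("x", "binary", 0.5),),
            PiecewiseHazardSpec((), (1e-9,), ((0.0,),)),
        )
        with pytest.raises(ValueError, match="unattainable"):
            calibrate_censoring(scen, target_rate=0.5)

    def test_scenario_event_rate_lands_in_printed_band(self):
        cohort = simulate_cohort(SCENARIOS["1.1"], seed=3)
        rate = np.mean([s.event for s in cohort])
        assert 0.05 <= rate <= 0.10


class TestCohortSimulation:
    def test_deterministic_given_seed(self):
        a = simulate_cohort(SCENARIOS["1.1"], seed=11)
        b = simulate_cohort(SCENARIOS["1.1"], seed=11)
        assert all(
            (x.id, x.time, x.event, x.covariates) == (y.id, y.time, y.event, y.covariates)
            for x, y in zip(a, b)
        )

    def test_cohort_size_and_fields(self):
        cohort = simulate_cohort(SCENARIOS["3.1"], seed=1)
        assert len(cohort) == 2000
        assert all(len(s.covariates) == 2 for s in cohort)
        xs = np.array([s.covariates[0] for s in cohort])
        assert set(np.unique(xs)) <= {0.0, 1.0}

    def test_zero_censor_bound_rejected(self):
        with pytest.raises(ValueError, match="bound"):
            simulate_cohort(SCENARIOS["1.1"], seed=0, censor_bound=0.0)


class TestCaseCohortSampling:
    def test_structure_subcohort_plus_outside_cases(self):
        cohort = simulate_cohort(SCENARIOS["1.1"], seed=21)
        data = sample_casecohort(cohort, m=500, seed=0)
        assert data.m_subcohort == 500
        outside = [s for s in data.subjects if not s.in_subcohort]
        assert all(s.event == 1 for s in outside)
        cases_total = sum(s.event for s in cohort)
        assert data.n_events == cases_total  # every cohort case is retained

    def test_m_equals_n_returns_whole_cohort(self):
        cohort = simulate_cohort(SCENARIOS["1.1"], seed=22)
        data = sample_casecohort(cohort, m=2000, seed=0, allow_full=True)
        assert len(data.subjects) == 2000
        with pytest.raises(ValueError):
            sample_casecohort(cohort, m=2000, seed=0)

    def test_inclusion_frequency_close_to_sampling_fraction(self):
        rng_ids = 40
        cohort = simulate_cohort(
            dataclasses.replace(SCENARIOS["1.1"], n_cohort=rng_ids, m_subcohort=10),
            seed=5,
        )
        m, reps = 10, 600
        freq = np.zeros(rng_ids)
        for s in range(reps):
            data = sample_casecohort(cohort, m=m, seed=s)
            ids = {x.id for x in data.subjects if x.in_subcohort}
            for i, subj in enumerate(cohort):
                freq[i] += subj.id in ids
        freq /= reps
        se = np.sqrt(0.25 * 0.75 / reps)
        assert np.all(np.abs(freq - m / rng_ids) < 4 * se)


class TestScenarioRegistry:
    def test_all_twelve_registered(self):
        assert sorted(SCENARIOS) == [
            "1.1", "1.2", "1.3", "1.4", "1.5",
            "2.1", "2.2", "2.3",
            "3.1", "3.2", "3.3", "3.4",
        ]
        for spec in SCENARIOS.values():
            assert spec.n_cohort == 2000 and spec.m_subcohort == 500

    def test_printed_parameters(self):
        s11 = SCENARIOS["1.1"].hazard
        assert s11.cutpoints == (0.3, 0.5, 0.8)
        # unexposed baseline at half the exposed rates, constant HR 2 for exposed
        assert np.allclose(s11.rates, (0.05, 0.1, 0.025, 0.05))
        assert np.allclose(
            np.asarray(s11.rates) * np.exp(s11.log_hr_matrix(1)[0]), (0.1, 0.2, 0.05, 0.1)
        )
        w22 = SCENARIOS["2.2"].hazard
        assert (w22.shape, w22.scale) == (1.5, 4.0)
        assert np.exp(w22.log_hr[0]) == pytest.approx(1.5)
        g14 = SCENARIOS["1.4"].hazard
        assert (g14.exposed.shape, g14.exposed.scale) == (0.3, 80.0)
        assert (g14.unexposed.shape, g14.unexposed.scale) == (0.6, 80.0)
        s23 = SCENARIOS["2.3"].hazard
        assert np.allclose(np.exp(s23.log_hr_matrix(1)[0]), (0.5, 0.5, 1.0, 1.0))
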
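"""Schoenfeld residuals, scaling, and the smoothed departure curve."""

import numpy as np
import pytest

from cchaz import (
    IntervalRecord,
    fit,
    scaled_residuals,
    schoenfeld_residuals,
    smooth_departure,
    to_counting_process,
)
from cchaz.residuals import ResidualTable
from cchaz.cox import PseudoLikelihoodFit

from conftest import random_full_cohort


class TestSchoenfeldResiduals:
    def test_zero_when_risk_set_is_homogeneous(self):
        # every member of the risk set shares the event subject's covariate
        records = [
            IntervalRecord("a", 0, 1.0, 1, (1.0,)),
            IntervalRecord("b", 0, 2.0, 1, (1.0,)),
            IntervalRecord("c", 0, 3.0, 0, (0.0,)),
        ]
        f = fit(records + [IntervalRecord("d", 0, 4.0, 0, (0.3,))])
        tab = schoenfeld_residuals(f, records[:2] + [IntervalRecord("c", 0, 0.5, 0, (1.0,))])
        assert np.allclose(tab.residuals, 0.0)

    def test_beta_zero_gives_arithmetic_risk_set_means(self, toy6_records):
        f = fit(toy6_records)
        tab = schoenfeld_residuals(f, toy6_records, beta=np.zeros(1))
        # events at t = 2, 2.5, 3.5, 4 with plain means 1/2, 1/4, 2/3, 1/2
        expected = np.array([1 - 0.5, 0 - 0.25, 1 - 2 / 3, 1 - 0.5])
        assert np.allclose(tab.residuals[:, 0], expected)

    def test_weighted_means_at_fitted_beta_on_toy6(self, toy6_records):
        f = fit(toy6_records)
        tab = schoenfeld_residuals(f, toy6_records)
        e = np.exp(f.beta[0])
        # brute-force weighted means over the hand-read risk sets
        expected = np.array([
            1 - 2 * e / (2 * e + 2),
            0 - e / (e + 3),
            1 - 2 * e / (2 * e + 1),
            1 - e / (e + 1),
        ])
        assert np.allclose(tab.residuals[:, 0], expected, atol=1e-10)
        assert abs(tab.residuals.sum()) <= 1e-6

    def test_rows_ordered_by_time_and_count_all_events(self, toy6, toy6_records):
        f = fit(toy6_records)
        tab = schoenfeld_residuals(f, toy6_records)
        assert tab.n_events == toy6.n_events == 4
        assert np.all(np.diff(tab.event_times) >= 0)
        # outside-subcohort cases E and F contribute rows too
        assert {"E", "F"} <= set(tab.event_ids)

    def test_column_sums_vanish_at_optimum(self):
        for seed in range(5):
            ds = random_full_cohort(seed, n=50, p=2)
            records = to_counting_process(ds)
            tab = schoenfeld_residuals(fit(records), records)
            assert np.all(np.abs(tab.residuals.sum(axis=0)) <= 1e-6)

    def test_invariant_to_covariate_shift(self):
        ds = random_full_cohort(11, n=40)
        records = to_counting_process(ds)
        shifted = [
            IntervalRecord(r.id, r.start, r.stop, r.event, tuple(c + 5.0 for c in r.covariates))
            for r in records
        ]
        t1 = schoenfeld_residuals(fit(records), records)
        t2 = schoenfeld_residuals(fit(shifted), shifted)
        assert np.allclose(t1.residuals, t2.residuals, atol=1e-7)


class TestScaledResiduals:
    def test_zero_residuals_map_to_beta(self):
        f = PseudoLikelihoodFit(
            beta=np.array([0.7]), covariance=np.array([[0.2]]), loglik=0.0,
            n_iter=1, converged=True, n_events=3,
        )
        tab = ResidualTable(np.array([1.0, 2, 3]), np.zeros((3, 1)),
                            np.array(["a", "b", "c"]), f.beta)
        assert np.allclose(scaled_residuals(f, tab), 0.7)

    def test_scalar_closed_form(self):
        f = PseudoLikelihoodFit(
            beta=np.array([0.4]), covariance=np.array([[0.05]]), loglik=0.0,
            n_iter=1, converged=True, n_events=4,
        )
        r = np.array([[0.1], [-0.3], [0.2], [0.0]])
        tab = ResidualTable(np.arange(1.0, 5.0), r, np.array(list("abcd")), f.beta)
        assert np.allclose(scaled_residuals(f, tab), 0.4 + 4 * 0.05 * r)

    def test_row_mean_recovers_beta(self):
        ds = random_full_cohort(2, n=60, p=2)
        records = to_counting_process(ds)
        f = fit(records)
        s = scaled_residuals(f, schoenfeld_residuals(f, records))
        assert np.allclose(s.mean(axis=0), f.beta, atol=1e-8)


class TestSmoothDeparture:
    def make_fit(self, d):
        return PseudoLikelihoodFit(
            beta=np.array([0.5]), covariance=np.array([[1.0 / d]]), loglik=0.0,
            n_iter=1, converged=True, n_events=d,
        )

    def table_from_scaled(self, times, target):
        """Residual rows chosen so the scaled residuals equal ``target``."""
        d = len(times)
        f = self.make_fit(d)
        r = (np.asarray(target) - f.beta[0]) / (d * f.covariance[0, 0])
        return f, ResidualTable(np.asarray(times), r.reshape(-1, 1),
                                np.array([f"e{i}" for i in range(d)]), f.beta)

    def test_constant_scaled_residuals_give_flat_curve(self):
        times = np.linspace(0.5, 5, 20)
        f, tab = self.table_from_scaled(times, np.full(20, 1.3))
        sm = smooth_departure(tab, f)
        assert np.allclose(sm.g_values, 1.3, atol=1e-9)

    def test_linear_scaled_residuals_reproduced_exactly(self):
        times = np.linspace(1, 4, 30)
        f, tab = self.table_from_scaled(times, 0.2 + 0.5 * times)
        sm = smooth_departure(tab, f)
        interior = (sm.grid_times > 1.2) & (sm.grid_times < 3.8)
        assert np.allclose(sm.g_values[interior], 0.2 + 0.5 * sm.grid_times[interior],
                           atol=1e-6)

    def test_band_brackets_estimate_and_grid_in_range(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0.5, 4, 40))
        f, tab = self.table_from_scaled(times, rng.normal(0.5, 0.3, 40))
        sm = smooth_departure(tab, f)
        assert np.all(sm.band_low <= sm.g_values) and np.all(sm.g_values <= sm.band_high)
        assert sm.grid_times.min() >= times.min() and sm.grid_times.max() <= times.max()

    def test_too_few_events_rejected(self):
        f, tab = self.table_from_scaled(np.linspace(1, 2, 5), np.ones(5))
        with pytest.raises(ValueError, match="too few events"):
            smooth_departure(tab, f)

    def test_nonph_scenario_curve_trends_with_generating_hazard_ratio(self):
        """Scenario 1.2's log-HR falls over time; G(t) should fall too."""
        from cchaz import SCENARIOS, simulate_casecohort

        data = simulate_casecohort(SCENARIOS["1.2"], seed=4)
        records = to_counting_process(data)
        f = fit(records)
        tab = schoenfeld_residuals(f, records)
        sm = smooth_departure(tab, f)
        early = sm.g_values[sm.grid_times < np.quantile(tab.event_times, 0.25)].mean()
        late = sm.g_values[sm.grid_times > np.quantile(tab.event_times, 0.75)].mean()
        assert early > late
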
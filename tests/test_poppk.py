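"""PK engine: closed-form vs ODE oracle, variability, allometry, half-life."""

import numpy as np
import pytest

from quinpk import (
    PKParameters,
    PopulationSpec,
    VirtualSubject,
    allometric_scale,
    apply_renal_impairment,
    build_treatment_schedule,
    default_time_grid,
    sample_individual,
    simulate_population,
    simulate_profile,
    terminal_half_life,
)
from quinpk.formulation import DoseEvent, DoseSchedule

from conftest import ode_profile


def _empty_schedule():
    return DoseSchedule((), 0.0, "flat")


class TestAnalyticVsODE:
    def test_single_dose_matches_ode_oracle(self, cq_params):
        sched = DoseSchedule((DoseEvent(0.0, 620.0, 4),), 1.0, "flat")
        grid = np.linspace(0.0, 240.0, 121)[1:]  # avoid t=0 (conc 0/0 in rel err)
        analytic = simulate_profile(cq_params, sched, grid).conc
        numeric = ode_profile(cq_params, sched, grid)
        mask = numeric > 1e-12
        rel = np.abs(analytic[mask] - numeric[mask]) / numeric[mask]
        assert rel.max() < 1e-6

    def test_multi_dose_matches_ode_oracle(self, cq_params, treatment_7d):
        grid = np.arange(1.0, 400.0, 7.0)
        analytic = simulate_profile(cq_params, treatment_7d, grid).conc
        numeric = ode_profile(cq_params, treatment_7d, grid)
        rel = np.abs(analytic - numeric) / np.maximum(numeric, 1e-12)
        assert rel.max() < 1e-6

    def test_mass_balance_in_ode_oracle(self, cq_params, treatment_7d):
        grid = np.arange(1.0, 300.0, 10.0)
        _, states = ode_profile(cq_params, treatment_7d, grid, track_elimination=True)
        dosed = np.array(
            [sum(e.amount for e in treatment_7d.events if e.time + cq_params.tlag <= t)
             for t in grid]
        )
        in_system = states.sum(axis=1)  # depot + central + peripheral + eliminated
        rel = np.abs(in_system - dosed) / dosed
        assert rel.max() < 1e-8


class TestLinearity:
    def test_empty_schedule_all_zero(self, cq_params):
        prof = simulate_profile(cq_params, _empty_schedule(), np.linspace(0, 48, 10))
        assert np.all(prof.conc == 0)

    def test_dose_linearity(self, cq_params, treatment_7d):
        grid = np.arange(0.0, 300.0, 5.0)
        base = simulate_profile(cq_params, treatment_7d, grid).conc
        doubled_sched = DoseSchedule(
            tuple(DoseEvent(e.time, 2 * e.amount, 2 * e.tablets) for e in treatment_7d.events),
            treatment_7d.duration,
            treatment_7d.strategy,
        )
        doubled = simulate_profile(cq_params, doubled_sched, grid).conc
        assert np.allclose(doubled, 2 * base, rtol=1e-12)

    def test_superposition_of_shifted_doses(self, cq_params):
        grid = np.arange(0.0, 200.0, 2.0)
        two = DoseSchedule(
            (DoseEvent(0.0, 620.0, 4), DoseEvent(12.0, 310.0, 2)), 1.0, "flat"
        )
        s1 = DoseSchedule((DoseEvent(0.0, 620.0, 4),), 1.0, "flat")
        s2 = DoseSchedule((DoseEvent(0.0, 310.0, 2),), 1.0, "flat")
        c_two = simulate_profile(cq_params, two, grid).conc
        c1 = simulate_profile(cq_params, s1, grid).conc
        c2 = simulate_profile(cq_params, s2, grid).conc
        shifted = np.interp(grid - 12.0, grid, c2, left=0.0)
        # the shifted profile is exact on grid points 12 h apart
        assert np.allclose(c_two, c1 + shifted, rtol=1e-9, atol=1e-12)

    def test_zero_before_lag(self, cq_params):
        sched = DoseSchedule((DoseEvent(0.0, 620.0, 4),), 1.0, "flat")
        grid = np.array([0.1, 0.25, 0.4, 0.49, 1.0])
        prof = simulate_profile(cq_params, sched, grid)
        assert np.all(prof.conc[grid < cq_params.tlag] == 0)
        assert prof.conc[-1] > 0


class TestAccumulation:
    def test_troughs_nondecreasing_under_repeated_dosing(self, cq_params):
        events = tuple(DoseEvent(24.0 * k, 155.0, 1) for k in range(30))
        sched = DoseSchedule(events, 30.0, "prophylaxis")
        troughs_t = np.arange(23.9, 24.0 * 30, 24.0)
        conc = simulate_profile(cq_params, sched, troughs_t).conc
        assert np.all(np.diff(conc) > -1e-12)


class TestVariability:
    def test_omega_zero_is_identity(self, cq_params):
        rng = np.random.default_rng(0)
        assert sample_individual(cq_params, 0.0, rng) == cq_params

    def test_lognormal_median_and_cv_recovery(self, cq_params):
        rng = np.random.default_rng(42)
        draws = np.array(
            [sample_individual(cq_params, 0.30, rng).cl_f for _ in range(100_000)]
        )
        assert np.median(draws) == pytest.approx(cq_params.cl_f, rel=0.01)
        gcv = np.sqrt(np.exp(np.var(np.log(draws))) - 1.0)
        assert gcv == pytest.approx(0.3069, abs=0.01)  # sqrt(exp(0.09)-1)

    def test_population_mean_cmax_exceeds_typical(self, cq_params):
        # lognormal mean > median: with omega=0.3 on volumes the mean peak
        # across subjects exceeds the typical-subject peak
        sched = DoseSchedule((DoseEvent(0.0, 620.0, 4),), 1.0, "flat")
        grid = np.arange(0.5, 48.0, 0.5)
        spec = PopulationSpec(n_subjects=4000, omega=0.3, seed=7)
        profiles = simulate_population(cq_params, sched, spec, grid)
        peaks = np.array([p.conc.max() for p in profiles])
        typical = simulate_profile(cq_params, sched, grid).conc.max()
        assert peaks.mean() > typical


class TestPopulation:
    def test_seeded_reproducibility(self, cq_params, treatment_7d):
        grid = np.arange(0.0, 100.0, 4.0)
        spec = PopulationSpec(n_subjects=20, omega=0.3, seed=11)
        a = simulate_population(cq_params, treatment_7d, spec, grid)
        b = simulate_population(cq_params, treatment_7d, spec, grid)
        assert all(np.array_equal(x.conc, y.conc) for x, y in zip(a, b))

    def test_degenerate_population_identical_to_typical(self, cq_params, treatment_7d):
        grid = np.arange(0.0, 100.0, 4.0)
        spec = PopulationSpec(n_subjects=5, omega=0.0, seed=1, weights=62.0)
        profiles = simulate_population(cq_params, treatment_7d, spec, grid)
        typical = simulate_profile(cq_params, treatment_7d, grid).conc
        for p in profiles:
            assert np.allclose(p.conc, typical, rtol=1e-12)


class TestAllometry:
    def test_reference_weight_is_identity(self, cq_params):
        spec = PopulationSpec()
        assert allometric_scale(cq_params, 62.0, spec) == cq_params

    def test_power_scaling(self, cq_params):
        spec = PopulationSpec()
        scaled = allometric_scale(cq_params, 124.0, spec)
        assert scaled.cl_f == pytest.approx(cq_params.cl_f * 2**0.75)
        assert scaled.vc_f == pytest.approx(cq_params.vc_f * 2.0)
        half = allometric_scale(cq_params, 31.0, spec)
        assert half.vc_f == pytest.approx(cq_params.vc_f / 2.0)

    def test_nonpositive_weight_rejected(self, cq_params):
        with pytest.raises(ValueError):
            allometric_scale(cq_params, 0.0, PopulationSpec())


class TestRenalImpairment:
    def test_worst_case_45_percent_reduction(self, cq_params):
        impaired = apply_renal_impairment(cq_params.replace(renal_fraction=0.5), 0.9)
        assert impaired.cl_f == pytest.approx(cq_params.cl_f * 0.55)

    def test_zero_impairment_identity(self, cq_params):
        assert apply_renal_impairment(cq_params, 0.0) == cq_params

    def test_fractional_renal_share(self, cq_params):
        impaired = apply_renal_impairment(cq_params.replace(renal_fraction=0.2), 1.0)
        assert impaired.cl_f == pytest.approx(cq_params.cl_f * 0.8)

    def test_out_of_range_rejected(self, cq_params):
        with pytest.raises(ValueError):
            apply_renal_impairment(cq_params, 1.5)

    def test_steady_state_average_raised_by_clearance_ratio(self, cq_params):
        # average steady-state concentration scales as 1/CL: the 45%
        # clearance reduction raises it by 1/0.55 under long dosing
        events = tuple(DoseEvent(24.0 * k, 155.0, 1) for k in range(600))
        sched = DoseSchedule(events, 600.0, "prophylaxis")
        window = np.arange(598 * 24.0, 600 * 24.0, 1.0)
        normal = simulate_profile(cq_params, sched, window).conc.mean()
        impaired_params = apply_renal_impairment(cq_params, 0.9)
        impaired = simulate_profile(impaired_params, sched, window).conc.mean()
        assert impaired / normal == pytest.approx(1 / 0.55, rel=0.02)


class TestHalfLife:
    def test_one_compartment_limit(self):
        p = PKParameters(cl_f=10.0, vc_f=100.0, q_f=1e-7, vp_f=1.0, ka=1.0)
        expected = np.log(2) * p.vc_f / p.cl_f
        assert terminal_half_life(p) == pytest.approx(expected, rel=1e-3)

    def test_exceeds_lumped_one_compartment_half_life(self, cq_params):
        lumped = np.log(2) * (cq_params.vc_f + cq_params.vp_f) / cq_params.cl_f
        assert terminal_half_life(cq_params) >= lumped * 0.999

    def test_matches_terminal_log_slope_of_simulation(self, cq_params):
        sched = DoseSchedule((DoseEvent(0.0, 620.0, 4),), 1.0, "flat")
        t = np.array([5000.0, 7000.0])  # deep terminal phase
        c = simulate_profile(cq_params, sched, t).conc
        slope = (np.log(c[1]) - np.log(c[0])) / (t[1] - t[0])
        assert np.log(2) / -slope == pytest.approx(terminal_half_life(cq_params), rel=1e-3)

    def test_fixture_half_life_exceeds_28_days(self, cq_params, hcq_params):
        assert terminal_half_life(cq_params) > 28 * 24
        assert terminal_half_life(hcq_params) > 28 * 24


class TestValidation:
    def test_negative_grid_rejected(self, cq_params, treatment_7d):
        with pytest.raises(ValueError):
            simulate_profile(cq_params, treatment_7d, np.array([-1.0, 1.0]))

    def test_parameter_positivity_enforced(self):
        with pytest.raises(ValueError):
            PKParameters(cl_f=-1.0, vc_f=100.0, q_f=1.0, vp_f=10.0, ka=1.0)
        with pytest.raises(ValueError):
            PKParameters(cl_f=1.0, vc_f=100.0, q_f=1.0, vp_f=10.0, ka=1.0, f_rel=1.5)

    def test_default_grid_covers_one_month_past_last_dose(self, treatment_7d):
        grid = default_time_grid(treatment_7d)
        assert grid[0] == 0.0
        assert grid[-1] == pytest.approx(treatment_7d.last_dose_time + 720.0)

    def test_two_peripheral_compartments_run(self, treatment_7d):
        p = PKParameters(
            cl_f=60.0, vc_f=1200.0, q_f=55.0, vp_f=30000.0, ka=0.4,
            q2_f=20.0, vp2_f=9000.0, n_peripheral=2,
        )
        grid = np.arange(0.0, 300.0, 5.0)
        prof = simulate_profile(p, treatment_7d, grid)
        assert np.all(prof.conc >= 0) and prof.conc.max() > 0
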
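"""Refractory-density core: hazard terms, transport, spike boundary."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import erf

from ictalwave import population as pop
from ictalwave.params import HazardParams, default_E_population


class TestHazard:
    def test_far_subthreshold_hazard_vanishes(self, hz_E):
        U = np.array([-90.0])
        H = pop.hazard(U, g_tot=hz_E.g_L, g_syn=0.0, V_th=-50.0,
                       dT_dt=0.0, params=hz_E)
        assert H[0] < 1e-12

    def test_drift_term_zero_for_nondecreasing_T(self, hz_E):
        B = pop.hazard_B(T=np.array([1.0, 0.0, -1.0]),
                         dT_dt=np.array([0.5, 0.0, 2.0]))
        assert np.all(B == 0.0)

    def test_drift_term_positive_for_approaching_threshold(self):
        assert pop.hazard_B(0.5, -0.1) > 0.0

    def test_noise_term_at_threshold_matches_printed_closed_form(self, hz_E):
        # T = 0: independent arbitrary-precision evaluation of the
        # printed polynomial/exponential expression
        for g_tot in (hz_E.g_L, 0.1, 1.0):
            got = float(pop.hazard_A(0.0, g_tot, hz_E))
            want = _hazard_A_reference_sympy(0.0, g_tot, hz_E)
            assert got == pytest.approx(want, rel=1e-10)

    def test_noise_term_against_high_precision_at_generic_T(self, hz_E):
        for T in (-1.0, 0.5, 2.0, 4.0):
            got = float(pop.hazard_A(T, 0.05, hz_E))
            want = _hazard_A_reference_sympy(T, 0.05, hz_E)
            assert got == pytest.approx(want, rel=1e-10)

    def test_invalid_conductance_raises(self, hz_E):
        with pytest.raises(FloatingPointError):
            pop.hazard(np.array([-60.0]), g_tot=0.0, g_syn=0.0,
                       V_th=-50.0, dT_dt=0.0, params=hz_E)
        with pytest.raises(FloatingPointError):
            pop.hazard(np.array([np.nan]), g_tot=0.05, g_syn=0.0,
                       V_th=-50.0, dT_dt=0.0, params=hz_E)

    def test_drift_term_stable_deep_above_threshold(self):
        # erfcx route: finite, growing ~ sqrt(pi)|T| for strongly
        # suprathreshold states
        B = pop.hazard_B(np.array([-5.0, -20.0]), np.array([-1.0, -1.0]))
        assert np.all(np.isfinite(B))
        assert B[1] > B[0] > 0

    @given(T=st.floats(-10, 10), dT=st.floats(-5, 5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_hazard_nonnegative(self, T, dT):
        hz = HazardParams(g_L=1.0 / 28.0)
        val = pop.hazard_A(T, 0.05, hz) + pop.hazard_B(T, dT)
        assert np.isfinite(val) and val >= 0.0


def _hazard_A_reference_sympy(T, g_tot, hz):
    import sympy as sp
    tau_m = sp.Rational(1) * hz.C / g_tot
    k = tau_m / hz.tau_noise
    Tm = sp.Float(max(T, pop.T_POLY_CLAMP), 40)
    poly = (sp.Float("0.0061", 40) - sp.Float("1.12", 40) * Tm
            - sp.Float("0.257", 40) * Tm**2 - sp.Float("0.072", 40) * Tm**3
            - sp.Float("0.0117", 40) * Tm**4)
    corr = 1 - (1 + k) ** (sp.Float("-0.71", 40)
                           + sp.Float("0.0825", 40) * (Tm + 3))
    return float(sp.exp(poly) * corr / tau_m)


class TestDriftTermIdentity:
    def test_matches_erf_formula_where_stable(self):
        # direct formula 2 sqrt(2/pi) [-dT]_+ exp(-T^2)/(1+erf(T))
        for T in (-2.0, 0.0, 1.5, 3.0):
            direct = 2 * np.sqrt(2 / np.pi) * 1.0 * np.exp(-T**2) / (1 + erf(T))
            assert float(pop.hazard_B(T, -1.0)) == pytest.approx(direct, rel=1e-10)


class TestTransport:
    def test_pure_shift_conserves_mass(self, rng):
        rho = rng.random(50)
        rho /= rho.sum()
        out, fired = pop.advance_density(rho, np.zeros(50), dt=0.1)
        assert fired == 0.0
        assert out.sum() == pytest.approx(1.0, abs=1e-15)
        np.testing.assert_allclose(out[1:-1], rho[:-2])
        assert out[-1] == pytest.approx(rho[-2] + rho[-1])

    def test_zero_density_stays_zero(self):
        out, fired = pop.advance_density(np.zeros(20), np.ones(20), 0.1)
        assert np.all(out == 0.0) and fired == 0.0

    def test_sink_against_fine_step_reference(self):
        # uniform density, constant hazard: removed mass per step equals
        # the Richardson-refined integral of rho*H within O(dt^2)
        n, H, dt = 100, 0.3, 0.5
        rho = np.full(n, 1.0 / n)
        _, fired = pop.advance_density(rho, np.full(n, H), dt)
        # fine reference: subdivide the step
        sub = 64
        mass = rho.copy()
        removed = 0.0
        for _ in range(sub):
            m2 = mass * np.exp(-H * dt / sub)
            removed += mass.sum() - m2.sum()
            mass = m2
        assert fired == pytest.approx(removed, rel=1e-12)
        assert fired == pytest.approx(rho.sum() * H * dt, rel=0.1)

    def test_firing_rate_trivial_cases(self):
        assert pop.firing_rate(np.zeros(10), np.ones(10), 0.1) == 0.0
        assert pop.firing_rate(np.ones(10) / 10, np.zeros(10), 0.1) == 0.0

    def test_transport_step_conserves_mass_and_shifts_state(self, rng):
        state = pop.PopulationState.resting(30, -70.0)
        state.rho = rng.random(30)
        state.rho /= state.rho.sum()
        state.U = rng.uniform(-80, -40, 30)
        U_old = state.U.copy()
        fired = pop.transport_step(state, np.full(30, 0.2), dt=0.5)
        total = state.rho.sum() + fired
        assert total == pytest.approx(1.0, abs=1e-14)
        np.testing.assert_allclose(state.U[2:-1], U_old[1:-2])


class TestSpikeBoundary:
    def test_no_mass_enters_when_no_firing(self):
        p = default_E_population()
        state = pop.PopulationState.resting(40, -70.0)
        pop.apply_spike_boundary(state, 0.0, 39, p, n_frozen=3)
        assert state.rho[0] == 0.0

    def test_printed_reset_values(self):
        p = default_E_population()
        state = pop.PopulationState.resting(40, -70.0)
        pop.apply_spike_boundary(state, 0.1, 39, p, n_frozen=3)
        assert p.V_reset == -40.0 and p.n_DR_reset == 0.5
        assert np.all(state.U[:3] == -40.0)
        assert np.all(state.n_DR[:3] == 0.5)

    def test_release_peak_matches_exhaustive_scan(self, rng):
        rho = rng.random(64)
        H = rng.random(64)
        idx = pop.spike_release_peak(rho, H)
        prod = rho * H
        assert all(prod[idx] >= prod[i] for i in range(64))

    def test_slow_gates_inherit_release_peak_value(self):
        p = default_E_population()
        state = pop.PopulationState.resting(40, -70.0)
        state.n_KCa[:] = np.linspace(0, 1, 40)
        pop.apply_spike_boundary(state, 0.05, 17, p, n_frozen=2)
        assert state.n_KCa[0] == pytest.approx(np.linspace(0, 1, 40)[17])


class TestDynamicThreshold:
    def test_half_shift_at_block_voltage(self, pop_E):
        _, V_th = pop.update_dynamic_threshold(pop_E.V_DB, pop_E.V_DB, 0.0, pop_E)
        assert V_th == pytest.approx(pop_E.V_th0 + pop_E.DB_shift / 2)

    def test_base_threshold_far_below_block(self, pop_E):
        _, V_th = pop.update_dynamic_threshold(-120.0, -120.0, 0.0, pop_E)
        assert V_th == pytest.approx(pop_E.V_th0, abs=1e-8)

    def test_sigmoid_value_by_independent_evaluation(self, pop_E):
        U_inf = -33.0
        _, V_th = pop.update_dynamic_threshold(U_inf, U_inf, 0.0, pop_E)
        expected = pop_E.V_th0 + pop_E.DB_shift / (
            1.0 + np.exp(-(U_inf - pop_E.V_DB) / pop_E.DB_slope))
        assert V_th == pytest.approx(expected, rel=1e-12)

    def test_low_pass_relaxation(self, pop_E):
        U_inf, _ = pop.update_dynamic_threshold(-70.0, -50.0, 100.0, pop_E)
        # after one tau the gap shrinks by 1/e
        assert float(U_inf) == pytest.approx(-50.0 - 20.0 * np.exp(-1.0))


class TestMassConservationLongRun:
    def test_thousand_steps_drift_below_tolerance(self):
        from ictalwave import oracle
        spec = oracle.EnsembleSpec(N=1, duration=100.0, dt=0.1,
                                   pop=oracle.validation_population())
        # direct reuse of the reference integrator, checking mass each call
        hz = HazardParams(g_L=spec.pop.g_L)
        nb = int(round(100.0 / spec.dt)) + 1
        state = pop.PopulationState.resting(nb, -70.0)
        total0 = state.total_mass()
        for s in range(1000):
            H = np.full(nb, 0.02)
            H[:3] = 0.0
            fired = pop.transport_step(state, H, spec.dt)
            pop.apply_spike_boundary(state, fired,
                                     pop.spike_release_peak(state.rho, H),
                                     spec.pop, 2)
        assert abs(state.total_mass() - total0) < 1e-6
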
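"""Nernst potentials, transporters, pumps, calcium, glia, volume."""

import numpy as np
import pytest

from ictalwave import ions
from ictalwave.params import IonParams


@pytest.fixture
def io():
    return IonParams()


class TestNernst:
    def test_equal_concentrations_zero_potential(self):
        r = ions.nernst_potentials(5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 16.0, 16.0)
        for v in (r.V_K, r.V_Cl, r.V_Na):
            assert float(v) == pytest.approx(0.0, abs=1e-12)

    def test_potassium_value_by_independent_arithmetic(self):
        r = ions.nernst_potentials(129.0, 5.0, 17.0, 3.5, 130.0, 130.0,
                                   16.0, 24.0)
        assert float(r.V_K) == pytest.approx(26.6 * np.log(3.5 / 129.0),
                                             rel=1e-12)

    def test_chloride_ratio_invariance(self):
        r1 = ions.nernst_potentials(129.0, 5.0, 17.0, 3.5, 130.0, 130.0, 16, 24)
        r2 = ions.nernst_potentials(129.0, 10.0, 17.0, 3.5, 260.0, 130.0, 16, 24)
        assert float(r1.V_Cl) == pytest.approx(float(r2.V_Cl), rel=1e-12)

    def test_gaba_mixture_above_chloride(self, io):
        # 4:1 Cl:HCO3 permeability with the printed bicarbonate levels
        r = ions.nernst_potentials(io.K_i0, io.Cl_i_E0, io.Na_i0, io.K_o0,
                                   io.Cl_o0, io.Na_o0, io.HCO3_i, io.HCO3_o)
        assert float(r.V_GABA) > float(r.V_Cl)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(FloatingPointError):
            ions.nernst_potentials(0.0, 5.0, 17.0, 3.5, 130.0, 130.0, 16, 24)


class TestTransporters:
    def test_kcc2_vanishes_at_equilibrium(self):
        assert float(ions.kcc2_flux(-80.0, -80.0, 1.0)) == 0.0

    def test_kcc2_exports_when_chloride_above_potassium_equilibrium(self):
        # V_Cl > V_K: KCl efflux (negative = out, influx-positive sign
        # convention shared with NKCC1)
        assert float(ions.kcc2_flux(-95.0, -85.0, 1.0)) < 0.0

    def test_kcc2_denominator_guard(self):
        # singular point V_Cl - V_K = -40 mV is clamped, not infinite
        val = ions.kcc2_flux(-50.0, -90.0, 1.0)
        assert np.isfinite(float(val))

    def test_nkcc1_vanishes_at_its_equilibrium(self):
        # V_Na + V_K = 2 V_Cl
        assert float(ions.nkcc1_flux(-90.0, -20.0, 50.0, 0.1)) == pytest.approx(0.0)

    def test_nkcc1_saturates_at_transporter_maximum(self):
        assert float(ions.nkcc1_flux(-95.9, -71.0, 54.1, 0.1)) == pytest.approx(0.1)
        assert float(ions.nkcc1_flux(-90.0, 0.0, 50.0, 0.1)) == pytest.approx(-0.1)

    def test_simple_pump_quarter_maximum_at_sigmoid_midpoints(self):
        # [K+]_o = 3.5, [Na+]_i = 25: both sigmoid arguments zero
        val = ions.pump_current_simple(3.5, 25.0, 0.8)
        assert float(val) == pytest.approx(0.8 / 4.0, rel=1e-12)


class TestKineticPump:
    def test_monotone_in_internal_sodium(self):
        na = np.linspace(5.0, 40.0, 30)
        vals = [float(ions.pump_current_kinetic(-70.0, 129.0, 3.5, n, 130.0, 0.8))
                for n in na]
        assert np.all(np.diff(vals) > 0)

    def test_monotone_in_external_potassium(self):
        ko = np.linspace(1.0, 15.0, 30)
        vals = [float(ions.pump_current_kinetic(-70.0, 129.0, k, 17.0, 130.0, 0.8))
                for k in ko]
        assert np.all(np.diff(vals) > 0)

    def test_resting_value_against_independent_symbolic_transcription(self):
        import sympy as sp
        U, Ki, Ko, Nai, Nao = sp.Float(-0.07, 30), 129, sp.Rational(7, 2), 17, 130
        nai = Nai / (sp.Float(2.49, 30) * sp.exp(sp.Float(-0.386, 30) * U))
        nae = Nao / (sp.Float(15.5, 30) * sp.exp(sp.Float(12.1, 30) * U))
        ki = Ki / sp.Rational(1, 2)
        ke = Ko / sp.Float(0.213, 30)
        H = sp.Float(1e-4, 30)
        mg = sp.Float(3.904, 30)
        Pi = sp.Float(4.2, 30) / (1 + sp.Rational(129, 292) + H / sp.Float(6.77, 30)
                                  + sp.Rational(17, 224))
        di = (1 + nai) ** 3 + (1 + ki) ** 2 - 1
        de = (1 + nae) ** 3 + (1 + ke) ** 2 - 1
        a1p = 1050 * nai**3 / di
        a2p = sp.Integer(481)
        a3p = 2000 * ke**2 / de
        a4p = 320 * mg / (1 + mg)
        a1m = sp.Float(8.605, 30)
        a2m = 40 * nae**3 / de
        a3m = 79300 * Pi * H / (1 + mg)
        a4m = 40 * ki**2 / di
        S = (a2p * a3p * a4p + a1m * a3p * a4p + a1m * a2m * a4p + a1m * a2m * a3m
             + a3p * a4p * a1p + a2m * a4p * a1p + a2m * a3m * a1p + a2m * a3m * a4m
             + a4p * a1p * a2p + a3m * a1p * a2p + a3m * a4m * a2p + a3m * a4m * a1m
             + a1p * a2p * a3p + a4m * a2p * a3p + a4m * a1m * a3p + a4m * a1m * a2m)
        expected = float((a1p * a2p * a3p * a4p - a1m * a2m * a3m * a4m)
                         / (sp.Float(16.8, 30) * S)) * 0.8
        got = float(ions.pump_current_kinetic(-70.0, 129.0, 3.5, 17.0, 130.0, 0.8))
        assert got == pytest.approx(expected, rel=1e-10)


class TestBalances:
    def test_zero_currents_zero_drift(self, io):
        rev = ions.nernst_potentials(io.K_i0, io.Cl_i_E0, io.Na_i0, io.K_o0,
                                     io.Cl_o0, io.Na_o0, io.HCO3_i, io.HCO3_o)
        # evaluate the RHS with every current zeroed explicitly
        io2 = IonParams(g_KL=0.0, g_ClL=0.0, g_NaL=0.0)
        dK, dCl, dNa = ions.intracellular_rhs(
            -70.0, rev, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, io2, is_E=True,
            Ca_i=0.0)
        assert dK == 0.0 and dCl == 0.0 and dNa == 0.0

    def test_spike_sodium_load_is_linear_in_rate(self, io):
        rev = ions.nernst_potentials(io.K_i0, io.Cl_i_E0, io.Na_i0, io.K_o0,
                                     io.Cl_o0, io.Na_o0, io.HCO3_i, io.HCO3_o)
        io2 = IonParams(g_KL=0.0, g_ClL=0.0, g_NaL=0.0)
        _, _, dNa = ions.intracellular_rhs(
            -70.0, rev, 0.0, 0.0, 0.0, 0.05, 0.0, 0.0, 0.0, io2, is_E=True,
            Ca_i=0.0)
        assert float(dNa) == pytest.approx(io.gamma * io.q_Na * 0.05, rel=1e-12)

    def test_intra_extra_exchange_conserves_matter(self, io):
        # the beta-weighted intracellular change plus the v-weighted
        # extracellular change must vanish without external sources
        st = ions.IonVolumeState.resting(4, io)
        dK_E = np.full(4, 2e-4); dK_I = np.full(4, -1e-4)
        dCl_E = np.full(4, 1e-4); dCl_I = np.full(4, 3e-4)
        dNa_E = np.full(4, -2e-4); dNa_I = np.full(4, 1e-4)
        pK, pCl, pNa = ions.advance_extracellular(
            st, dK_E, dK_I, dCl_E, dCl_I, dNa_E, dNa_I,
            G=np.zeros(4), diffusion=np.zeros(4),
            p=IonParams(D_bath=0.0), dt=1.0)
        w = lambda e, i: (1 - io.alpha_I) * e + io.alpha_I * i
        for p_new, p_old, di in ((pK, st.K_o, w(dK_E, dK_I)),
                                 (pCl, st.Cl_o, w(dCl_E, dCl_I)),
                                 (pNa, st.Na_o, w(dNa_E, dNa_I))):
            total_change = (p_new - st.v * p_old) + io.beta * di * 1.0
            np.testing.assert_allclose(total_change, 0.0, atol=1e-13)

    def test_bath_relaxation_closed_form(self, io):
        # no activity: K_o relaxes exponentially toward K_bath at D_bath/v
        st = ions.IonVolumeState.resting(1, io)
        st.K_o[:] = 8.0
        z = np.zeros(1)
        k = st.K_o.copy()
        dt = 1.0
        for _ in range(4000):
            pK, _, _ = ions.advance_extracellular(
                st, z, z, z, z, z, z, z, z, io, dt)
            st.K_o = pK / st.v
        expected = io.K_bath + (8.0 - io.K_bath) * np.exp(-io.D_bath * 4000 * dt)
        assert float(st.K_o[0]) == pytest.approx(float(expected), rel=1e-3)


class TestCalciumGliaVolume:
    def test_calcium_pure_decay_at_200ms(self, io):
        ca = 1e-3
        for _ in range(200):
            ca = ions.advance_calcium(ca, 0.0, -60.0, io, 1.0)
        assert float(np.ravel(ca)[0]) == pytest.approx(1e-3 * np.exp(-1.0), rel=1e-2)

    def test_calcium_reversal_gives_pure_decay(self, io):
        a = ions.advance_calcium(1e-3, 0.5, io.V_Ca, io, 1.0)
        b = ions.advance_calcium(1e-3, 0.0, -60.0, io, 1.0)
        assert float(a) == pytest.approx(float(b), rel=1e-12)

    def test_calcium_steady_state_closed_form(self, io):
        g, U = 0.01, -60.0
        ca = 0.0
        for _ in range(5000):
            ca = ions.advance_calcium(ca, g, U, io, 1.0)
        expected = io.tau_Ca * io.chi * g * (io.V_Ca - U)
        assert float(np.ravel(ca)[0]) == pytest.approx(expected, rel=1e-2)

    def test_glia_disabled_exact_zero(self, io):
        B, G = ions.glial_buffer_step(np.array([500.0]), np.array([10.0]),
                                      io, 1.0)
        assert float(G[0]) == 0.0 and float(B[0]) == 500.0

    def test_glia_low_potassium_release_rate_vanishes(self):
        io = IonParams(glia_on=True)
        # k2 -> 0 for K_o << 15 mM with the printed sigmoid, so a full
        # (free) buffer is stationary at rest
        B, G = ions.glial_buffer_step(np.array([io.B_max]), np.array([3.5]),
                                      io, 1.0)
        assert abs(float(G[0])) < 1e-6

    def test_glia_binds_potassium_when_elevated(self):
        io = IonParams(glia_on=True)
        B, G = ions.glial_buffer_step(np.array([io.B_max]), np.array([20.0]),
                                      io, 1.0)
        assert float(G[0]) < 0.0 and float(B[0]) < io.B_max

    def test_volume_rest_fixed_point(self, io):
        st = ions.IonVolumeState.resting(1, io)
        dpi0 = ions.osmolarity_baseline(io)
        v = ions.advance_volume(st, io, 1e6, dpi0)
        assert float(v[0]) == pytest.approx(1.0, abs=1e-9)

    def test_volume_fixed_point_under_constant_osmotic_load(self, io):
        st = ions.IonVolumeState.resting(1, io)
        st.Na_i_E[:] += 10.0
        st.Na_i_I[:] += 10.0   # cells gained 10 mM osmolytes
        dpi0 = ions.osmolarity_baseline(io)
        for _ in range(100):
            st.v = ions.advance_volume(st, io, 50.0, dpi0)
        expected = 1.0 + io.vol_factor * io.beta0 * (np.exp(-10.0 / io.osm_scale) - 1)
        assert float(st.v[0]) == pytest.approx(float(expected), rel=1e-6)
        assert float(st.v[0]) < 1.0  # ECS shrinks when cells swell

    def test_fixed_volume_mode(self, io):
        io2 = IonParams(volume_dynamic=False)
        st = ions.IonVolumeState.resting(3, io2)
        st.Na_i_E[:] += 30.0
        v = ions.advance_volume(st, io2, 10.0, ions.osmolarity_baseline(io2))
        np.testing.assert_array_equal(v, 1.0)


class TestRestingClosure:
    def test_pump_scale_balances_resting_potassium(self, io):
        scale = ions.pump_rest_scale(io)
        rev = ions.nernst_potentials(io.K_i0, io.Cl_i_E0, io.Na_i0, io.K_o0,
                                     io.Cl_o0, io.Na_o0, io.HCO3_i, io.HCO3_o)
        g = io.g_KL + io.g_ClL + io.g_NaL
        V_L = float((io.g_KL * rev.V_K + io.g_ClL * rev.V_Cl
                     + io.g_NaL * rev.V_Na) / g)
        Ip = scale * float(ions.pump_current(V_L, io.K_o0, io.K_i0,
                                             io.Na_i0, io.Na_o0, io))
        kcc2 = float(ions.kcc2_flux(rev.V_K, rev.V_Cl, io.I_KCC2_max_E))
        I_K_leak = io.g_KL * (V_L - float(rev.V_K))
        assert 2 * Ip == pytest.approx(I_K_leak - kcc2, rel=1e-10)

    def test_offsets_make_printed_state_stationary(self, io):
        offs = ions.resting_flux_offsets(io, ions.pump_rest_scale(io))
        # potassium and sodium exactly stationary; chloride left free
        assert offs.shape == (2, 3)
        assert np.all(offs[:, 1] == 0.0)
        # recomputing the resting RHS minus offsets gives zero K/Na drift
        for ip, cl in enumerate((io.Cl_i_E0, io.Cl_i_I0)):
            rev = ions.nernst_potentials(io.K_i0, cl, io.Na_i0, io.K_o0,
                                         io.Cl_o0, io.Na_o0, io.HCO3_i, io.HCO3_o)
            g = io.g_KL + io.g_ClL + io.g_NaL
            V_L = float((io.g_KL * rev.V_K + io.g_ClL * rev.V_Cl
                         + io.g_NaL * rev.V_Na) / g)
            Ip = ions.pump_rest_scale(io) * float(ions.pump_current(
                V_L, io.K_o0, io.K_i0, io.Na_i0, io.Na_o0, io))
            kcc2 = ions.kcc2_flux(rev.V_K, rev.V_Cl,
                                  io.I_KCC2_max_E if ip == 0 else io.I_KCC2_max_I)
            nk = ions.nkcc1_flux(rev.V_K, rev.V_Cl, rev.V_Na,
                                 io.I_NKCC1_max_E if ip == 0 else io.I_NKCC1_max_I)
            dK, _, dNa = ions.intracellular_rhs(
                V_L, rev, 0.0, 0.0, 0.0, 0.0, Ip, kcc2, nk, io,
                is_E=(ip == 0), Ca_i=0.0)
            assert float(dK) - offs[ip, 0] == pytest.approx(0.0, abs=1e-15)
            assert float(dNa) - offs[ip, 2] == pytest.approx(0.0, abs=1e-15)
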
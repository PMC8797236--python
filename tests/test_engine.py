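"""Engine-level behaviour: noise, observables, determinism, scenarios."""

import dataclasses

import numpy as np
import pytest
from scipy.special import erfcx

from ictalwave import engine, synapses
from ictalwave import currents as cur
from ictalwave.params import (ScenarioConfig, SpatialParams,
                              apply_scenario_preset, desk_config)


def tiny_config(**kw):
    base = dict(duration=5.0, dt=1.0, t_star_max=60.0, seed=3,
                spatial=SpatialParams(n_x=12))
    base.update(kw)
    return ScenarioConfig(**base)


class TestOuNoise:
    def test_long_run_stationary_sd_within_two_percent(self):
        rng = np.random.default_rng(0)
        sigma, tau, dt = 0.8333, 4.0, 0.5
        n = 1_000_000
        f = np.exp(-dt / tau)
        s = sigma * np.sqrt(1 - f * f)
        x = np.empty(n)
        acc = 0.0
        normals = rng.standard_normal(n)
        for i in range(n):
            acc = acc * f + s * normals[i]
            x[i] = acc
        assert np.std(x[1000:]) == pytest.approx(sigma, rel=0.02)

    def test_vanishing_step_vanishing_increment(self):
        rng = np.random.default_rng(1)
        out = engine.ou_noise_step(0.0, 1e-9, 4.0, 1.0, rng)
        assert abs(float(out)) < 1e-4

    def test_fixed_seed_bitwise_identical_streams(self):
        g1 = engine.noise_generators(42, 8)
        g2 = engine.noise_generators(42, 8)
        for a, b in zip(g1, g2):
            np.testing.assert_array_equal(a.standard_normal(100),
                                          b.standard_normal(100))

    def test_streams_independent_of_node_count(self):
        # the first node's stream is unchanged when more nodes exist
        a = engine.noise_generators(7, 4)[0].standard_normal(50)
        b = engine.noise_generators(7, 16)[0].standard_normal(50)
        np.testing.assert_array_equal(a, b)


class TestHoldingCurrent:
    def test_all_conductances_zero(self):
        assert engine.holding_current_observable(0.0, 0.0, 0.0, -70.0) == 0.0

    def test_pure_gaba_event_positive_outward(self):
        I = engine.holding_current_observable(0.1, 0.0, 0.0, V_GABA=-70.0)
        assert float(I) > 0.0

    def test_pure_glutamatergic_event_negative(self):
        I = engine.holding_current_observable(0.0, 0.1, 0.05, V_GABA=-70.0)
        assert float(I) < 0.0


class TestLookupTables:
    def test_tables_match_exact_functions(self):
        cfg = tiny_config()
        TU, T_EXPN, T_G, T_A, T_Q, GRID = engine.build_tables(cfg)
        ug = engine.U_LO + np.arange(TU.shape[1]) / engine.U_PER
        np.testing.assert_allclose(TU[0], synapses.nmda_block(ug, 0.25),
                                   rtol=1e-12)
        aD, bD = cur.alpha_DR(ug), cur.beta_DR(ug)
        np.testing.assert_allclose(TU[1], aD / (aD + bD), rtol=1e-12)
        np.testing.assert_allclose(TU[2], np.exp(-(aD + bD) * cfg.dt),
                                   rtol=1e-12)
        xg = np.arange(T_EXPN.size) / engine.E_PER
        np.testing.assert_allclose(T_EXPN, np.exp(-xg), rtol=1e-12)
        tg = engine.T_LO + np.arange(T_A.size) / engine.T_PER
        np.testing.assert_allclose(T_G, 1.0 / erfcx(-tg), rtol=1e-10)
        np.testing.assert_allclose(T_A, engine._a_poly(tg), rtol=1e-12)

    def test_interpolation_error_small_between_nodes(self):
        cfg = tiny_config()
        TU, T_EXPN, T_G, T_A, T_Q, GRID = engine.build_tables(cfg)
        # exp(-x) table: midpoint linear-interpolation error
        xs = (np.arange(200) + 0.5) / engine.E_PER
        idx = (xs * engine.E_PER).astype(int)
        approx = 0.5 * (T_EXPN[idx] + T_EXPN[idx + 1])
        np.testing.assert_allclose(approx, np.exp(-xs), atol=5e-6)


class TestRunScenario:
    def test_recording_structure_and_finiteness(self):
        rec = engine.run_scenario(tiny_config())
        assert rec.validate()
        assert np.all(np.diff(rec.t_trace) > 0)
        assert rec.trace.shape[1] == len(rec.columns)

    def test_density_mass_conserved_through_full_dynamics(self):
        rec = engine.run_scenario(tiny_config(duration=20.0))
        for colname in ("mass_E", "mass_I"):
            m = rec.col(colname)
            assert np.all(np.abs(m - 1.0) < 1e-6)

    def test_same_seed_identical_recordings(self):
        r1 = engine.run_scenario(tiny_config(duration=8.0))
        r2 = engine.run_scenario(tiny_config(duration=8.0))
        np.testing.assert_array_equal(r1.trace, r2.trace)
        np.testing.assert_array_equal(r1.fields, r2.fields)

    def test_different_seeds_differ(self):
        r1 = engine.run_scenario(tiny_config(duration=8.0, seed=1))
        r2 = engine.run_scenario(tiny_config(duration=8.0, seed=2))
        assert not np.array_equal(r1.trace, r2.trace)

    def test_zero_noise_rest_is_quiet(self):
        # without the noise source the coupled E/I system emits no
        # spikes; concentrations move only through the slow chloride
        # loading that paces epileptogenesis
        rec = engine.run_scenario(tiny_config(duration=10.0, noise_pA=0.0))
        assert float(rec.col("nu_E_S1").max()) < 1e-6
        assert float(rec.col("nu_I_S1").max()) < 1e-6
        assert abs(float(rec.col("K_o_S1")[-1]) - 3.5) < 1.0
        assert float(rec.col("Na_i_E_S1")[-1]) == pytest.approx(17.0, abs=0.2)

    def test_sealed_system_baseline_holds(self):
        # no bath exchange, no diffusion, no glia, fixed volume, no
        # noise: the potassium/sodium closure keeps those baselines
        # while chloride drifts monotonically (the epileptogenic clock)
        cfg = tiny_config(duration=10.0, noise_pA=0.0)
        cfg.ions = dataclasses.replace(cfg.ions, D_bath=0.0,
                                       volume_dynamic=False)
        cfg.spatial = dataclasses.replace(cfg.spatial, D_1d=0.0)
        rec = engine.run_scenario(cfg)
        assert float(rec.col("nu_E_S1").max()) < 1e-6
        na = rec.col("Na_i_E_S1")
        assert abs(na[-1] - 17.0) < 0.5
        cl = rec.col("Cl_i_E_S1")
        assert cl[-1] > cl[0]                       # clock is running
        assert np.all(np.diff(cl[10:]) > -1e-9)     # monotone loading
        assert np.all(rec.col("v_S1") == 1.0)       # fixed-volume mode


class TestScenarioPresets:
    def test_long_connections_binding(self):
        cfg = apply_scenario_preset(ScenarioConfig(scenario="long_connections"))
        assert cfg.spatial.lam == pytest.approx(0.25)

    def test_high_diffusion_binding(self):
        cfg = apply_scenario_preset(ScenarioConfig(scenario="high_diffusion",
                                                   dt=0.1))
        assert cfg.spatial.D_1d == pytest.approx(390e-6)
        assert cfg.spatial.lam == 0.0

    def test_no_diffusion_binding(self):
        cfg = apply_scenario_preset(ScenarioConfig(scenario="no_diffusion"))
        assert cfg.spatial.D_1d == 0.0

    def test_all_to_all_binding(self):
        cfg = apply_scenario_preset(ScenarioConfig(scenario="all_to_all"))
        assert cfg.spatial.all_to_all_fraction == pytest.approx(0.2)

    def test_fixed_volume_and_glia_bindings(self):
        assert apply_scenario_preset(
            ScenarioConfig(scenario="fixed_volume")).ions.volume_dynamic is False
        assert apply_scenario_preset(
            ScenarioConfig(scenario="glial_buffer")).ions.glia_on is True

    def test_preset_does_not_mutate_input(self):
        cfg = ScenarioConfig(scenario="long_connections")
        apply_scenario_preset(cfg)
        assert cfg.spatial.lam == pytest.approx(0.05)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(scenario="lunar")

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(dt=-0.1)


class TestAllScenariosRun:
    @pytest.mark.parametrize("scenario", ["local_only", "high_diffusion",
                                          "fixed_volume", "glial_buffer"])
    def test_scenario_completes_and_is_finite(self, scenario):
        cfg = tiny_config(duration=3.0)
        cfg.scenario = scenario
        rec = engine.run_scenario(cfg)
        assert rec.validate()
        if scenario == "fixed_volume":
            assert np.all(rec.col("v_S1") == 1.0)


class TestRefinement:
    def test_slow_observables_consistent_across_dt(self):
        # halving dt leaves the slow ionic observables of a quiet run
        # essentially unchanged (numerical-scheme consistency)
        vals = {}
        for dt in (1.0, 0.5):
            cfg = tiny_config(duration=20.0, dt=dt, noise_pA=0.0)
            cfg.ions = dataclasses.replace(cfg.ions, rest_offsets=False)
            rec = engine.run_scenario(cfg)
            vals[dt] = np.array([rec.col("K_o_S1")[-1],
                                 rec.col("Cl_i_I_S1")[-1],
                                 rec.col("Na_i_E_S1")[-1]])
        np.testing.assert_allclose(vals[1.0], vals[0.5], rtol=2e-2)
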
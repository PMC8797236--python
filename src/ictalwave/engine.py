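"""Simulation engine: scenario orchestration on the (t, t*, x) grid.

Builds the full coupled state (two CBRD populations, six synaptic
channels, ion/volume fields, representative neurons), compiles the
lookup tables used by the fused kernel, generates per-node
Ornstein-Uhlenbeck noise, and integrates the named scenarios with the
operator-splitting order: noise -> spatial kernels -> synapses ->
population transport/voltage/hazard -> representative neurons -> ion
balances -> glia -> volume -> observables. Runs are deterministic
given the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
from scipy.special import erfcx

from . import _kernel as K
from . import currents as cur
from . import ions as ion_mod
from . import population as pop_mod
from . import spatial as sp_mod
from . import synapses as syn_mod
from .params import ScenarioConfig, apply_scenario_preset

TRACE_NAMES_SITE = ("K_o", "U_E", "U_I", "nu_E", "nu_I", "V_repE", "V_repI",
                    "I_hold", "V_GABA_E", "V_GABA_I", "Na_i_E", "Cl_i_E",
                    "Cl_i_I", "v", "Ca_i")
TRACE_NAMES_EXTRA = ("mass_E", "mass_I", "x_glu", "x_gaba")
FIELD_NAMES = ("U_E", "K_o", "Cl_i_E", "Na_i_E", "v")


def trace_column_names():
    cols = []
    for site in ("S1", "S2"):
        cols += [f"{n}_{site}" for n in TRACE_NAMES_SITE]
    cols += list(TRACE_NAMES_EXTRA)
    return cols


@dataclass
class Recording:
    """Time series at the virtual electrodes plus space-time fields."""

    t_trace: np.ndarray          # s
    trace: np.ndarray            # (n, n_signals)
    columns: tuple
    t_fields: np.ndarray         # s
    fields: np.ndarray           # (n, len(FIELD_NAMES), n_x)
    field_names: tuple
    x: np.ndarray                # mm
    electrode_idx: tuple
    electrode_x: tuple
    config: ScenarioConfig

    def col(self, name):
        return self.trace[:, self.columns.index(name)]

    @property
    def electrode_distance(self):
        return abs(self.electrode_x[1] - self.electrode_x[0])

    def validate(self):
        if np.any(np.diff(self.t_trace) <= 0):
            raise ValueError("non-monotone time base")
        if not (np.all(np.isfinite(self.trace))
                and np.all(np.isfinite(self.fields))):
            raise FloatingPointError("non-finite values in recording")
        return True


# --- lookup tables -------------------------------------------------------

U_LO, U_HI, U_PER = -120.0, 60.0, 32       # U grid
E_HI, E_PER = 40.0, 256                    # exp(-x) grid
T_LO, T_HI, T_PER = -12.0, 10.0, 128       # T grid (A and G tables)
TQ_PER = 16                                # Q-table T resolution
QG_LO, QG_HI, QG_PER = 0.01, 6.51, 32      # Q-table conductance axis


def _a_poly(T):
    Tc = np.maximum(T, pop_mod.T_POLY_CLAMP)
    return np.exp(0.0061 - 1.12 * Tc - 0.257 * Tc**2
                  - 0.072 * Tc**3 - 0.0117 * Tc**4)


def build_tables(cfg: ScenarioConfig):
    dt = cfg.dt
    ug = np.arange(U_LO, U_HI + 0.5 / U_PER, 1.0 / U_PER)
    nU = ug.size
    TU = np.empty((6, nU))
    TU[0] = syn_mod.nmda_block(ug, cfg.synapses.Mg)
    aD, bD = cur.alpha_DR(ug), cur.beta_DR(ug)
    TU[1] = aD / (aD + bD)
    TU[2] = np.exp(-(aD + bD) * dt)
    aM, bM = cur.alpha_M(ug), cur.beta_M(ug)
    TU[3] = aM / (aM + bM)
    TU[4] = np.exp(-(aM + bM) * dt)
    pE = cfg.pop_E
    TU[5] = 1.0 / (1.0 + np.exp(-(ug - pE.V_DB) / pE.DB_slope))

    xg = np.arange(0.0, E_HI + 0.5 / E_PER, 1.0 / E_PER)
    T_EXPN = np.exp(-xg)

    tg = np.arange(T_LO, T_HI + 0.5 / T_PER, 1.0 / T_PER)
    T_A = _a_poly(tg)
    T_G = 1.0 / erfcx(-tg)

    tq = np.arange(T_LO, T_HI + 0.5 / TQ_PER, 1.0 / TQ_PER)
    gq = np.arange(QG_LO, QG_HI + 0.5 / QG_PER, 1.0 / QG_PER)
    tau_n = cfg.noise_tau
    kk = pE.C / (gq[None, :] * tau_n)
    cc = -0.71 + 0.0825 * (np.maximum(tq, pop_mod.T_POLY_CLAMP)[:, None] + 3.0)
    T_Q = 1.0 - (1.0 + kk) ** cc
    T_Q = np.maximum(T_Q, 0.0)

    GRID = np.zeros(K.G_LEN)
    GRID[K.G_U0] = U_LO; GRID[K.G_IDU] = U_PER; GRID[K.G_NU] = nU
    GRID[K.G_E0] = 0.0; GRID[K.G_IDE] = E_PER; GRID[K.G_NE] = T_EXPN.size
    GRID[K.G_T0] = T_LO; GRID[K.G_IDT] = T_PER; GRID[K.G_NT] = T_A.size
    GRID[K.G_Q_G0] = QG_LO; GRID[K.G_Q_IDG] = QG_PER; GRID[K.G_Q_NG] = gq.size
    return TU, T_EXPN, T_G, T_A, T_Q, GRID


# --- parameter vector ----------------------------------------------------

def build_param_vector(cfg: ScenarioConfig, grid: sp_mod.SpatialGrid):
    p = np.zeros(K.P_LEN)
    pE, pI, io, sy = cfg.pop_E, cfg.pop_I, cfg.ions, cfg.synapses
    dt = cfg.dt
    p[K.P_DT] = dt
    p[K.P_NF] = cfg.n_frozen
    p[K.P_GL_E] = pE.g_L
    p[K.P_GL_I] = pI.g_L
    p[K.P_VTH0_E] = pE.V_th0
    p[K.P_VTH0_I] = pI.V_th0
    p[K.P_VRESET] = pE.V_reset
    p[K.P_NDR_RESET] = pE.n_DR_reset
    p[K.P_VDB] = pE.V_DB
    p[K.P_DBSLOPE] = pE.DB_slope
    p[K.P_DBSHIFT] = pE.DB_shift
    p[K.P_FUINF] = np.exp(-dt / pE.tau_Uinf)
    p[K.P_SIGMA0] = 3.0
    p[K.P_SIG_LINEAR] = float(cfg.sigma_v_linear)
    p[K.P_GABA_LITERAL] = float(cfg.gaba_drive_literal)
    p[K.P_GDR_E] = pE.g_DR
    p[K.P_GM_E] = pE.g_M
    p[K.P_GKCA_E] = pE.g_KCa
    p[K.P_GDR_I] = pI.g_DR
    p[K.P_AKCA] = cur.ALPHA_KCA
    p[K.P_BKCA] = cur.BETA_KCA
    p[K.P_CAP] = pE.C
    p[K.P_GA_I] = sy.AMPA_I.g_max
    p[K.P_GN_E] = sy.NMDA_E.g_max
    p[K.P_GN_I] = sy.NMDA_I.g_max
    p[K.P_GG_E] = sy.GABA_E.g_max
    p[K.P_GG_I] = sy.GABA_I.g_max
    p[K.P_UGLU] = sy.u_glu if cfg.depression_on else 0.0
    p[K.P_UGABA] = sy.u_GABA if cfg.depression_on else 0.0
    p[K.P_TAUGLU] = sy.tau_glu
    p[K.P_TAUGABA] = sy.tau_GABA
    p[K.P_FOU] = np.exp(-dt / cfg.noise_tau)
    p[K.P_SOU] = cfg.noise_sigma * np.sqrt(1.0 - np.exp(-2.0 * dt / cfg.noise_tau))
    p[K.P_VHOLD] = cfg.V_hold
    p[K.P_FNMDA_HOLD] = float(syn_mod.nmda_block(cfg.V_hold, sy.Mg))
    p[K.P_GAMMA] = io.gamma
    p[K.P_BETAR] = io.beta
    p[K.P_ALPHAI] = io.alpha_I
    p[K.P_IPUMPMAX] = io.I_pump_max * ion_mod.pump_rest_scale(io)
    p[K.P_KCC2_E] = io.I_KCC2_max_E
    p[K.P_KCC2_I] = io.I_KCC2_max_I
    p[K.P_NKCC1_E] = io.I_NKCC1_max_E
    p[K.P_NKCC1_I] = io.I_NKCC1_max_I
    p[K.P_GKL] = io.g_KL
    p[K.P_GCLL] = io.g_ClL
    p[K.P_GNAL] = io.g_NaL
    p[K.P_QNA] = io.q_Na
    p[K.P_DBATH] = io.D_bath
    p[K.P_KBATH] = io.K_bath
    p[K.P_FRKGLU] = io.frac_K_glu
    p[K.P_FRNAGLU] = io.frac_Na_glu
    p[K.P_TAUCA] = io.tau_Ca
    p[K.P_CHI] = io.chi
    p[K.P_VCA] = io.V_Ca
    p[K.P_GLIA] = float(io.glia_on)
    p[K.P_K1] = io.k1
    p[K.P_BMAX] = io.B_max
    p[K.P_VOLDYN] = float(io.volume_dynamic)
    p[K.P_FVOL] = 1.0 - np.exp(-dt / io.tau_v)
    p[K.P_VOLFAC] = io.vol_factor * io.beta0
    p[K.P_OSM] = io.osm_scale
    p[K.P_DPI0] = ion_mod.osmolarity_baseline(io)
    p[K.P_HCO3I] = io.HCO3_i
    p[K.P_HCO3O] = io.HCO3_o
    p[K.P_DDX2] = cfg.spatial.D_1d / grid.dx**2
    p[K.P_ALLFRAC] = cfg.spatial.all_to_all_fraction
    p[K.P_PUMPKIN] = float(io.pump_kinetic)
    p[K.P_KCC2PRINT] = float(cfg.kcc2_literal_sign)
    p[K.P_NERNST] = 26.6
    p[K.P_GNA_REP] = cur.RepresentativeNeuron.G_NA
    p[K.P_VNA_REP] = cur.RepresentativeNeuron.V_NA
    p[K.P_REPSUB] = max(1, int(round(dt / 0.1)))
    p[K.P_S1] = grid.s1
    p[K.P_S2] = grid.s2
    p[K.P_TRSTR] = max(1, int(round(cfg.trace_stride_ms / dt)))
    p[K.P_FLSTR] = max(1, int(round(cfg.field_stride_ms / dt)))
    p[K.P_NB] = cfg.n_bins
    p[K.P_NX] = cfg.spatial.n_x
    p[K.P_SIGOU] = cfg.noise_sigma if cfg.noise_in_hazard else 0.0
    p[K.P_TAUN] = cfg.noise_tau
    p[K.P_GABACL] = float(cfg.gaba_cl_split)
    p[K.P_PUMPV] = float(io.pump_in_voltage)
    scale = ion_mod.pump_rest_scale(io)
    vE, vI = resting_voltages(cfg)
    p[K.P_IPREST_E] = scale * float(ion_mod.pump_current(
        vE, io.K_o0, io.K_i0, io.Na_i0, io.Na_o0, io))
    p[K.P_IPREST_I] = scale * float(ion_mod.pump_current(
        vI, io.K_o0, io.K_i0, io.Na_i0, io.Na_o0, io))
    return p


# --- state construction --------------------------------------------------

@dataclass
class EngineState:
    rho: np.ndarray
    U: np.ndarray
    Uinf: np.ndarray
    Tprev: np.ndarray
    nDR: np.ndarray
    nM: np.ndarray
    nKCa: np.ndarray
    nu: np.ndarray
    syn_m: np.ndarray
    syn_md: np.ndarray
    xglu: np.ndarray
    xgaba: np.ndarray
    ION: np.ndarray
    Inoise: np.ndarray
    PUMP: np.ndarray
    REP: np.ndarray


def resting_voltages(cfg: ScenarioConfig):
    """Leak-mixture resting voltage per population at initial ion levels."""
    io = cfg.ions
    vr = []
    for cl_i in (io.Cl_i_E0, io.Cl_i_I0):
        rev = ion_mod.nernst_potentials(io.K_i0, cl_i, io.Na_i0,
                                        io.K_o0, io.Cl_o0, io.Na_o0,
                                        io.HCO3_i, io.HCO3_o)
        g = io.g_KL + io.g_ClL + io.g_NaL
        vr.append(float((io.g_KL * rev.V_K + io.g_ClL * rev.V_Cl
                         + io.g_NaL * rev.V_Na) / g))
    return tuple(vr)


def initial_state(cfg: ScenarioConfig) -> EngineState:
    nx, nb = cfg.spatial.n_x, cfg.n_bins
    vE, vI = resting_voltages(cfg)
    rho = np.zeros((2, nx, nb))
    rho[:, :, -1] = 1.0
    U = np.empty((2, nx, nb))
    U[0] = vE
    U[1] = vI
    Uinf = U.copy()
    Tprev = np.full((2, nx, nb), 10.0)
    nDR = np.empty((2, nx, nb))
    for p, v0 in enumerate((vE, vI)):
        nDR[p] = float(cur.alpha_DR(v0) / (cur.alpha_DR(v0) + cur.beta_DR(v0)))
    nM = np.full((nx, nb), float(cur.alpha_M(vE)
                                 / (cur.alpha_M(vE) + cur.beta_M(vE))))
    nKCa = np.zeros((nx, nb))
    nu = np.zeros((2, nx))
    syn_m = np.zeros((6, nx))
    syn_md = np.zeros((6, nx))
    xglu = np.ones(nx)
    xgaba = np.ones(nx)
    ion_state = ion_mod.IonVolumeState.resting(nx, cfg.ions)
    ION = np.stack([ion_state.K_i_E, ion_state.K_i_I,
                    ion_state.Cl_i_E, ion_state.Cl_i_I,
                    ion_state.Na_i_E, ion_state.Na_i_I,
                    ion_state.K_o, ion_state.Cl_o, ion_state.Na_o,
                    ion_state.Ca_i_E, ion_state.B, ion_state.v])
    Inoise = np.zeros(nx)
    scale = ion_mod.pump_rest_scale(cfg.ions)
    PUMP = np.empty((2, nx))
    for ip, v0 in enumerate((vE, vI)):
        PUMP[ip] = scale * float(ion_mod.pump_current(
            v0, cfg.ions.K_o0, cfg.ions.K_i0, cfg.ions.Na_i0,
            cfg.ions.Na_o0, cfg.ions))
    REP = np.zeros((4, 9))
    for r in range(4):
        v0 = vE if r < 2 else vI
        REP[r, 0] = v0
        REP[r, 1] = float(cur.alpha_m_Na(v0) / (cur.alpha_m_Na(v0) + cur.beta_m_Na(v0)))
        REP[r, 2] = float(cur.alpha_h_Na(v0) / (cur.alpha_h_Na(v0) + cur.beta_h_Na(v0)))
        REP[r, 3] = float(cur.alpha_DR(v0) / (cur.alpha_DR(v0) + cur.beta_DR(v0)))
        REP[r, 4] = float(cur.alpha_M(v0) / (cur.alpha_M(v0) + cur.beta_M(v0)))
        REP[r, 6] = v0
        REP[r, 8] = v0
    return EngineState(rho=rho, U=U, Uinf=Uinf, Tprev=Tprev, nDR=nDR,
                       nM=nM, nKCa=nKCa, nu=nu, syn_m=syn_m, syn_md=syn_md,
                       xglu=xglu, xgaba=xgaba, ION=ION, Inoise=Inoise,
                       PUMP=PUMP, REP=REP)


def synapse_propagators(cfg: ScenarioConfig):
    """Per-channel homogeneous 2x2 propagators and source gains."""
    sy = cfg.synapses
    order = (sy.AMPA_E, sy.AMPA_I, sy.NMDA_E, sy.NMDA_I, sy.GABA_E, sy.GABA_I)
    prop = np.empty((6, 2, 2))
    src = np.empty(6)
    for k, spk in enumerate(order):
        prop[k] = syn_mod.homogeneous_propagator(spk, cfg.dt)
        src[k] = syn_mod.tau_s(spk.tau_r, spk.tau_d) / (spk.tau_r * spk.tau_d)
    return prop, src


def noise_generators(seed, n_x):
    """Independent per-node Philox streams split from the master seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.Philox(s)) for s in ss.spawn(n_x)]


def ou_noise_step(state, dt, tau, sigma, rng):
    """Exact OU update: decay plus scaled Gaussian increment.

    Stationary SD equals ``sigma``; used by the engine via pregenerated
    per-node normal increments.
    """
    f = np.exp(-dt / tau)
    s = sigma * np.sqrt(1.0 - f * f)
    return state * f + s * rng.standard_normal(np.shape(state))


def holding_current_observable(g_GABA, g_AMPA, g_NMDA, V_GABA, V_hold=-27.0,
                               Mg=0.25):
    """Synaptic current at the clamp voltage (uA/cm^2).

    I = g_GABA (V_hold - V_GABA) + g_AMPA V_hold
        + g_NMDA f_NMDA(V_hold) V_hold  (V_AMPA = V_NMDA = 0).
    GABAergic events are positive (outward) at -27 mV; glutamatergic
    events are negative.
    """
    f = syn_mod.nmda_block(V_hold, Mg)
    return (np.asarray(g_GABA, float) * (V_hold - np.asarray(V_GABA, float))
            + np.asarray(g_AMPA, float) * V_hold
            + np.asarray(g_NMDA, float) * f * V_hold)


# --- main entry ----------------------------------------------------------

def run_scenario(config: ScenarioConfig, progress=None) -> Recording:
    """Integrate one scenario and return its Recording.

    Applies the scenario preset, builds the state and tables, and steps
    the fused kernel in chunks. Aborts with a diagnostic on numerical
    blow-up. Deterministic for a fixed seed.
    """
    cfg = apply_scenario_preset(config)
    grid = sp_mod.SpatialGrid(cfg.spatial)
    W = sp_mod.connection_kernel(grid, cfg.spatial.lam)
    gA_E_prof = sp_mod.ampa_gradient_profile(
        grid, cfg.synapses.AMPA_E.g_max, enabled=cfg.spatial.ampa_gradient)
    P = build_param_vector(cfg, grid)
    OFFS = ion_mod.resting_flux_offsets(cfg.ions,
                                        ion_mod.pump_rest_scale(cfg.ions))
    tables = build_tables(cfg)
    st = initial_state(cfg)
    prop, src = synapse_propagators(cfg)
    gens = noise_generators(cfg.seed, cfg.spatial.n_x)

    n_steps = int(round(cfg.duration * 1000.0 / cfg.dt))
    tr_str = int(P[K.P_TRSTR])
    fl_str = int(P[K.P_FLSTR])
    n_tr = (n_steps - 1) // tr_str + 1
    n_fl = (n_steps - 1) // fl_str + 1
    trace = np.zeros((n_tr, 34))
    fields = np.zeros((n_fl, len(FIELD_NAMES), cfg.spatial.n_x))

    chunk = 20000
    s0 = 0
    while s0 < n_steps:
        n = min(chunk, n_steps - s0)
        normals = np.column_stack([g.standard_normal(n) for g in gens])
        K.run_chunk(s0, n, P, W, gA_E_prof, OFFS,
                    st.rho, st.U, st.Uinf, st.Tprev, st.nDR, st.nM, st.nKCa,
                    st.nu, st.syn_m, st.syn_md, prop, src, st.xglu, st.xgaba,
                    st.ION, st.Inoise, st.PUMP, st.REP, normals, *tables,
                    trace, fields)
        if not np.all(np.isfinite(st.ION)):
            raise FloatingPointError(
                f"numerical blow-up at t = {(s0 + n) * cfg.dt / 1000.0:.1f} s;"
                " last valid state dumped in the returned diagnostics")
        s0 += n
        if progress is not None:
            progress(s0, n_steps)

    rec = Recording(
        t_trace=np.arange(n_tr) * tr_str * cfg.dt / 1000.0,
        trace=trace,
        columns=tuple(trace_column_names()),
        t_fields=np.arange(n_fl) * fl_str * cfg.dt / 1000.0,
        fields=fields,
        field_names=FIELD_NAMES,
        x=grid.x,
        electrode_idx=(grid.s1, grid.s2),
        electrode_x=(float(grid.x[grid.s1]), float(grid.x[grid.s2])),
        config=cfg,
    )
    rec.validate()
    return rec
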
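"""Model parameters and scenario configuration.

Units used throughout the package: mV, ms, mM, mm (space),
uA/cm^2 (currents), mS/cm^2 (conductances), uF/cm^2 (capacitance).
Conductances that the literature quotes in uS/cm^2 are stored in mS/cm^2
(1 uS/cm^2 = 1e-3 mS/cm^2) so that g * V directly yields uA/cm^2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
NERNST_MV = 26.6  # RT/F at slice temperature, mV


@dataclass
class HazardParams:
    """Parameters of the hazard function of a single population.

    The hazard converts the distance of the mean voltage to the spike
    threshold, scaled by the voltage noise amplitude, into an
    instantaneous firing probability rate.
    """

    sigma_V0: float = 3.0        # resting voltage noise SD, mV
    tau_noise: float = 4.0       # noise correlation time, ms
    C: float = 1.0               # membrane capacitance, uF/cm^2
    g_L: float = 1.0 / 28.0      # leak conductance, mS/cm^2
    V_th_base: float = -50.0     # base spike threshold, mV
    sigma_v_linear: bool = False  # use the linear (1+g_syn/g_L) noise scaling
    # stationary SD of the stochastic synaptic-bombardment current the
    # population receives (uA/cm^2); its voltage-filtered dispersion adds
    # in quadrature to sigma_V in the hazard (0 for populations without it)
    sigma_ou_current: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_V0 <= 0 or self.tau_noise <= 0 or self.C <= 0 or self.g_L <= 0:
            raise ValueError("hazard parameters must be positive")


@dataclass
class PopulationParams:
    """Per-population (E or I) membrane and threshold parameters."""

    kind: str                    # "E" or "I"
    tau_m0: float                # resting membrane time constant, ms
    V_th0: float                 # base threshold, mV
    g_DR: float = 4e-3           # delayed-rectifier max conductance, mS/cm^2
    g_M: float = 0.0             # M-current max conductance, mS/cm^2
    g_KCa: float = 0.0           # K-Ca (AHP) max conductance, mS/cm^2
    C: float = 1.0               # uF/cm^2
    V_reset: float = -40.0       # mV
    dt_AP: float = 1.5           # spike duration, ms
    n_DR_reset: float = 0.5
    V_DB: float = -40.0          # depolarization-block midpoint, mV
    # sigmoid width of the block threshold shift (mV). A wide tail makes
    # the threshold rise faster than the membrane potential well below
    # V_DB and silences the network; 2.5 mV confines the block to the
    # depolarized range (see docs/methods.md)
    DB_slope: float = 2.5
    DB_shift: float = 100.0      # mV added at full block
    tau_Uinf: float = 100.0      # low-pass time constant for U_inf, ms

    @property
    def g_L(self) -> float:
        """Lumped leak conductance of the voltage equation (mS/cm^2)."""
        return self.C / self.tau_m0


def default_E_population() -> PopulationParams:
    return PopulationParams(kind="E", tau_m0=28.0, V_th0=-50.0,
                            g_M=0.7e-3, g_KCa=0.4e-3)


def default_I_population() -> PopulationParams:
    return PopulationParams(kind="I", tau_m0=9.0, V_th0=-45.0)


@dataclass
class SynapseParams:
    """Kinetics and maxima of one synapse type onto one target population."""

    g_max: float                 # mS/cm^2
    tau_r: float                 # rise time constant, ms
    tau_d: float                 # decay time constant, ms
    E_rev: float = 0.0           # mV (GABA reversal is dynamic; ignored there)

    def __post_init__(self) -> None:
        if self.tau_r <= 0 or self.tau_d <= 0:
            raise ValueError("synaptic time constants must be positive")


@dataclass
class SynapsesParams:
    """All six (type, target) synaptic channels plus depression."""

    AMPA_E: SynapseParams = field(default_factory=lambda: SynapseParams(0.3, 1.7, 8.3))
    AMPA_I: SynapseParams = field(default_factory=lambda: SynapseParams(0.4, 1.7, 8.3))
    NMDA_E: SynapseParams = field(default_factory=lambda: SynapseParams(0.6, 6.7, 100.0))
    NMDA_I: SynapseParams = field(default_factory=lambda: SynapseParams(0.9, 6.7, 100.0))
    GABA_E: SynapseParams = field(default_factory=lambda: SynapseParams(1.0, 0.5, 20.0))
    GABA_I: SynapseParams = field(default_factory=lambda: SynapseParams(2.0, 0.5, 20.0))
    Mg: float = 0.25             # mM
    tau_glu: float = 500.0       # depression recovery, ms
    tau_GABA: float = 500.0
    u_glu: float = 0.2           # utilization per presynaptic spike
    u_GABA: float = 0.1


@dataclass
class IonParams:
    """Ion balance, transporter, pump, calcium, glia and volume parameters."""

    gamma: float = 1e-3          # (mM/ms)/(uA/cm^2)
    beta: float = 10.0           # intra/extracellular volume ratio
    alpha_I: float = 0.25        # interneuron fraction
    I_pump_max: float = 0.8      # uA/cm^2
    I_KCC2_max_E: float = 1.0    # uA/cm^2
    I_KCC2_max_I: float = 1.0
    I_NKCC1_max_E: float = 0.0
    I_NKCC1_max_I: float = 0.1
    g_KL: float = 20e-3          # mS/cm^2
    g_ClL: float = 20e-3
    g_NaL: float = 7e-3
    q_Na: float = 0.1            # sodium charge per spike, uC/cm^2
    D_bath: float = 0.25e-3      # bath exchange rate, 1/ms (published value 0.25 1/s)
    K_bath: float = 3.5          # mM
    frac_K_glu: float = 0.2      # K fraction of glutamatergic conductance
    frac_Na_glu: float = 0.4
    # initial concentrations, mM
    K_o0: float = 3.5
    Cl_o0: float = 130.0
    Na_o0: float = 130.0
    K_i0: float = 129.0
    Cl_i_E0: float = 5.0
    Cl_i_I0: float = 9.0
    Na_i0: float = 17.0
    HCO3_i: float = 16.0
    HCO3_o: float = 24.0
    # calcium (E cells)
    tau_Ca: float = 200.0        # ms
    chi: float = 0.001           # mM/ms per (mS/cm^2 * mV)
    V_Ca: float = 20.0           # mV
    # glia
    glia_on: bool = False
    k1: float = 0.02e-3          # 1/ms (published value 0.02 1/s)
    B_max: float = 500.0         # mM
    # volume
    volume_dynamic: bool = True
    tau_v: float = 250.0         # ms
    beta0: float = 10.0
    osm_scale: float = 20.0      # mM, osmolarity scale of the volume law
    vol_factor: float = 0.1029
    pump_kinetic: bool = True    # full kinetic-cycle pump vs double sigmoid
    # normalize the pump so the published resting state is a K+ flux
    # equilibrium for E cells (the published cycle normalization is
    # under-determined; see docs/methods.md)
    pump_rest_balance: bool = True
    # subtract the residual passive flux at the published resting state so
    # that it is an exact equilibrium (see docs/methods.md); chloride is
    # exempt unless rest_offsets_cl — its slow passive loading is the
    # model's epileptogenic clock
    rest_offsets: bool = True
    rest_offsets_cl: bool = False
    # electrogenic pump current (net one charge out per cycle) in the
    # membrane equation, acting as its deviation from the resting pump;
    # this is the hyperpolarizing termination force of the discharge
    pump_in_voltage: bool = True


@dataclass
class SpatialParams:
    """1-D cortical segment geometry and coupling."""

    L: float = 2.5               # mm
    n_x: int = 64
    lam: float = 0.05            # Gaussian connection length, mm (50 um)
    D_1d: float = 0.39e-6        # K+ diffusion coefficient, mm^2/ms
    all_to_all_fraction: float = 0.0
    ampa_gradient: bool = True   # linear g_AMPA,E profile, 0 at x=0
    electrode_fracs: tuple = (0.25, 0.75)  # S1, S2 as fractions of L

    @property
    def dx(self) -> float:
        return self.L / (self.n_x - 1)

    def __post_init__(self) -> None:
        if self.n_x < 8:
            raise ValueError("n_x must be at least 8")
        if self.lam < 0 or self.D_1d < 0:
            raise ValueError("lambda and D_1d must be nonnegative")


SCENARIOS = (
    "control", "no_diffusion", "local_only", "high_diffusion",
    "long_connections", "all_to_all", "fixed_volume", "glial_buffer",
)


@dataclass
class ScenarioConfig:
    """Full configuration of one simulation run."""

    scenario: str = "control"
    duration: float = 400.0      # s
    dt: float = 0.5              # ms; also the t* bin width
    t_star_max: float = 120.0    # ms; last bin is absorbing
    seed: int = 0
    noise_pA: float = 25.0       # OU amplitude, pA
    noise_tau: float = 4.0       # ms
    membrane_area: float = 3e-5  # cm^2 (converts pA to uA/cm^2)
    V_hold: float = -27.0        # mV, holding potential of the virtual clamp
    trace_stride_ms: float = 10.0
    field_stride_ms: float = 100.0
    gaba_drive_literal: bool = False  # literal (V_K - U) GABA driving force
    # chloride balance uses the chloride component of the GABA-A current,
    # g_GABA * (4/5) * (U - V_Cl) (the 4:1 Cl:HCO3 permeability mixture);
    # False routes the full g_GABA (U - V_GABA) current to chloride
    gaba_cl_split: bool = True
    # fold the OU bombardment's voltage dispersion into the hazard noise
    # of the noise-receiving population (off: OU acts as common drive only)
    noise_in_hazard: bool = False
    sigma_v_linear: bool = False
    kcc2_literal_sign: bool = False   # audit: KCC2 numerator sign as originally published
    depression_on: bool = True
    spatial: SpatialParams = field(default_factory=SpatialParams)
    ions: IonParams = field(default_factory=IonParams)
    synapses: SynapsesParams = field(default_factory=SynapsesParams)
    pop_E: PopulationParams = field(default_factory=default_E_population)
    pop_I: PopulationParams = field(default_factory=default_I_population)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_star_max < 10 * self.dt:
            raise ValueError("t_star_max must cover at least 10 t* bins")
        # CFL check for explicit potassium diffusion
        dx = self.spatial.dx
        if self.spatial.D_1d * self.dt / dx**2 > 0.5:
            raise ValueError("diffusion CFL violated: reduce dt or D_1d")

    @property
    def n_bins(self) -> int:
        return int(round(self.t_star_max / self.dt)) + 1  # + absorbing bin

    @property
    def n_frozen(self) -> int:
        """Number of t* bins inside the spike window dt_AP."""
        return max(1, int(round(self.pop_E.dt_AP / self.dt)))

    @property
    def noise_sigma(self) -> float:
        """OU stationary SD as a current density, uA/cm^2."""
        return self.noise_pA * 1e-6 / self.membrane_area

    def electrode_indices(self) -> tuple:
        n = self.spatial.n_x
        i1, i2 = (int(round(f * (n - 1))) for f in self.spatial.electrode_fracs)
        if i1 == i2:
            raise ValueError("electrode sites coincide")
        return i1, i2


def desk_config(scenario="control", duration=300.0, seed=1,
                **overrides) -> ScenarioConfig:
    """Desk-scale configuration used by the test suite and the
    reproduction script: dt = 1 ms (one t* bin per step), 80 ms of
    explicitly resolved refractory history plus the absorbing bin, and
    48 spatial nodes over the 2.5 mm segment (dx = 53 um). These sizes
    keep a 300-400 s simulation in the minutes range on one core; the
    discharge regime is unchanged against finer settings (see
    docs/methods.md).
    """
    cfg = ScenarioConfig(scenario=scenario, duration=duration, seed=seed,
                         dt=1.0, t_star_max=80.0,
                         field_stride_ms=50.0,
                         spatial=SpatialParams(n_x=48), **overrides)
    return cfg


def apply_scenario_preset(cfg: ScenarioConfig) -> ScenarioConfig:
    """Return a copy of ``cfg`` with the scenario's parameter bindings applied.

    The bindings reproduce the published in-silico experiments: blockade of
    extracellular K+ diffusion, eliminated (lambda=0) or long (lambda=250 um)
    connections, a 1000x diffusion coefficient, a 0.2 all-to-all fraction,
    fixed ECS volume, and the glial buffer.
    """
    cfg = dataclasses.replace(cfg)
    cfg.spatial = dataclasses.replace(cfg.spatial)
    cfg.ions = dataclasses.replace(cfg.ions)
    s = cfg.scenario
    if s == "no_diffusion":
        cfg.spatial.D_1d = 0.0
    elif s == "local_only":
        cfg.spatial.lam = 0.0
    elif s == "high_diffusion":
        cfg.spatial.lam = 0.0
        cfg.spatial.D_1d = 390e-6  # mm^2/ms
    elif s == "long_connections":
        cfg.spatial.lam = 0.25     # mm
    elif s == "all_to_all":
        cfg.spatial.all_to_all_fraction = 0.2
    elif s == "fixed_volume":
        cfg.ions.volume_dynamic = False
    elif s == "glial_buffer":
        cfg.ions.glia_on = True
    return cfg
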
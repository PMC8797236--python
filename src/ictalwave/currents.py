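"""Voltage-gated ionic currents and gating kinetics.

Potassium currents of the population voltage equation (delayed rectifier,
M-type, and the calcium-dependent AHP current) and the explicit sodium
current of the representative single neuron. Rate functions of the
alpha/beta form contain removable singularities of the type
x/(exp(x)-1); these are evaluated by a short Taylor expansion within
+-1e-3 mV of the singular voltage so the rates are finite and continuous
everywhere.
"""

from __future__ import annotations

import numpy as np

_SING_EPS = 1e-3


def _lin_exp_ratio(x, scale):
    """Evaluate x / (exp(x/scale) - 1), resolving the removable singularity.

    Near x = 0: scale * (1 - u/2 + u^2/12) with u = x/scale (3-term Taylor,
    limit value -scale... note the limit of x/(exp(x/s)-1) at x->0 is s).
    """
    x = np.asarray(x, dtype=float)
    u = x / scale
    small = np.abs(x) < _SING_EPS
    u_safe = np.where(small, 1.0, u)
    with np.errstate(over="ignore"):
        out = np.where(small,
                       scale * (1.0 - u / 2.0 + u * u / 12.0),
                       x / np.expm1(u_safe))
    return out


def alpha_DR(U):
    """Delayed-rectifier activation rate, 1/ms. Singularity at U = -48 mV."""
    return 0.032 * _lin_exp_ratio(-(np.asarray(U, float) + 48.0), 5.0)


def beta_DR(U):
    return 0.5 * np.exp(-(np.asarray(U, float) + 53.0) / 40.0)


def alpha_M(U):
    """M-current activation rate, 1/ms. Singularity at U = -30 mV."""
    return 0.0001 * _lin_exp_ratio(-(np.asarray(U, float) + 30.0), 9.0)


def beta_M(U):
    """M-current deactivation rate, 1/ms. Singularity at U = -30 mV."""
    return 0.0001 * _lin_exp_ratio(np.asarray(U, float) + 30.0, 9.0)


# K-Ca (AHP) gating: dn/dt = ALPHA_KCA * Ca^2 * (1 - n) - BETA_KCA * n
ALPHA_KCA = 2000.0   # mM^-2 ms^-1
BETA_KCA = 0.002     # ms^-1


def alpha_m_Na(U):
    """Sodium activation rate (representative neuron). Singular at -50 mV."""
    return 0.32 * _lin_exp_ratio(-(np.asarray(U, float) + 50.0), 4.0)


def beta_m_Na(U):
    """Sodium deactivation rate; singular at U = -23 mV.

    The positive-exponent (Traub-family) form is used so the rate is
    nonnegative at all voltages.
    """
    return 0.28 * _lin_exp_ratio(np.asarray(U, float) + 23.0, 5.0)


def alpha_h_Na(U):
    return 0.128 * np.exp(-(np.asarray(U, float) + 46.0) / 18.0)


def beta_h_Na(U):
    return 4.0 / (1.0 + np.exp(-(np.asarray(U, float) + 23.0) / 5.0))


def voltage_gated_currents(U, n_DR, n_M, n_KCa, V_K, g_DR, g_M, g_KCa):
    """Return (I_DR, I_M, I_KCa) in uA/cm^2.

    I_DR = g_DR n^4 (U-V_K); I_M = g_M n_M (U-V_K);
    I_KCa = g_KCa n_KCa^2 (U-V_K). Conductances in mS/cm^2, voltages mV.
    """
    drive = np.asarray(U, float) - V_K
    I_DR = g_DR * np.asarray(n_DR, float) ** 4 * drive
    I_M = g_M * np.asarray(n_M, float) * drive
    I_KCa = g_KCa * np.asarray(n_KCa, float) ** 2 * drive
    return I_DR, I_M, I_KCa


def advance_gating(n, alpha, beta, dt):
    """Exponential-Euler update of dn/dt = alpha(1-n) - beta n.

    Relaxes toward alpha/(alpha+beta) at rate (alpha+beta); exact for
    constant rates and keeps n within [0, 1].
    """
    a = np.asarray(alpha, float)
    b = np.asarray(beta, float)
    r = a + b
    r_safe = np.where(r > 0, r, 1.0)
    n_inf = np.where(r > 0, a / r_safe, np.asarray(n, float))
    return n_inf + (np.asarray(n, float) - n_inf) * np.exp(-r * dt)


def advance_kca_gating(n, Ca, dt):
    """K-Ca gating step; the binding rate scales with [Ca]_i^2."""
    a = ALPHA_KCA * np.asarray(Ca, float) ** 2
    return advance_gating(n, a, BETA_KCA, dt)


def advance_population_voltage(U, g_L, V_L, I_K, g_GABA, V_GABA,
                               g_AMPA, g_NMDA_eff, I_noise, dt, C=1.0,
                               V_AMPA=0.0, V_NMDA=0.0):
    """Exponential-Euler step of the population (per-t*-bin) voltage.

    C dU/dt = -g_L(U-V_L) - I_K + I_noise + g_GABA(V_GABA-U)
              + g_AMPA(V_AMPA-U) + g_NMDA_eff(V_NMDA-U)

    I_K bundles the voltage-gated potassium currents evaluated at the
    current state (held over the step); g_NMDA_eff already includes the
    magnesium block at the current voltage. Raises on non-finite output.
    """
    U = np.asarray(U, float)
    g_tot = g_L + g_GABA + g_AMPA + g_NMDA_eff
    rhs0 = (g_L * V_L + g_GABA * V_GABA + g_AMPA * V_AMPA
            + g_NMDA_eff * V_NMDA - np.asarray(I_K, float) + I_noise)
    U_ss = rhs0 / g_tot
    out = U_ss + (U - U_ss) * np.exp(-g_tot * dt / C)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite population voltage")
    return out


class RepresentativeNeuron:
    """Single observer neuron driven by the same synaptic input as its
    population at one spatial node.

    Integrates the membrane equation as a total time derivative with the
    explicit sodium current I_Na = g_Na m^3 h (V - V_Na), plus the same
    threshold-and-reset convention as the population (dynamic threshold,
    reset to V_reset, frozen spike window). A +30 mV overshoot sample is
    emitted at each threshold crossing so that recorded traces show
    spikes. The neuron is a passive observer: it does not feed back into
    the population or ion dynamics.
    """

    G_NA = 7e-3   # mS/cm^2
    V_NA = 50.0   # mV
    OVERSHOOT = 30.0

    def __init__(self, pop_params, substeps=10):
        self.p = pop_params
        self.substeps = substeps
        self.spike_times = []

    def initialize(self, V0):
        self.V = float(V0)
        self.m = float(alpha_m_Na(V0) / (alpha_m_Na(V0) + beta_m_Na(V0)))
        self.h = float(alpha_h_Na(V0) / (alpha_h_Na(V0) + beta_h_Na(V0)))
        self.n_DR = float(alpha_DR(V0) / (alpha_DR(V0) + beta_DR(V0)))
        self.n_M = float(alpha_M(V0) / (alpha_M(V0) + beta_M(V0)))
        self.n_KCa = 0.0
        self.U_inf = float(V0)
        self.frozen_left = 0.0
        self.spike_times = []

    def step(self, t_ms, g_L, V_L, V_K, g_GABA, V_GABA, g_AMPA, g_NMDA,
             f_nmda_of_V, I_ext, dt, Ca=0.0):
        """Advance by dt (sub-stepped); return the voltage sample."""
        p = self.p
        h_dt = dt / self.substeps
        emitted = None
        for _ in range(self.substeps):
            if self.frozen_left > 0.0:
                self.frozen_left -= h_dt
                self.V = p.V_reset
                self.n_DR = p.n_DR_reset
            else:
                V = self.V
                I_Na = self.G_NA * self.m**3 * self.h * (V - self.V_NA)
                I_K = (p.g_DR * self.n_DR**4 + p.g_M * self.n_M
                       + p.g_KCa * self.n_KCa**2) * (V - V_K)
                g_nmda_eff = g_NMDA * f_nmda_of_V(V)
                dV = (-p.g_L * (V - V_L) - I_Na - I_K + I_ext
                      + g_GABA * (V_GABA - V) - g_AMPA * V
                      - g_nmda_eff * V) / p.C
                self.V = V + h_dt * dV
                self.m = float(advance_gating(self.m, alpha_m_Na(V), beta_m_Na(V), h_dt))
                self.h = float(advance_gating(self.h, alpha_h_Na(V), beta_h_Na(V), h_dt))
                self.n_DR = float(advance_gating(self.n_DR, alpha_DR(V), beta_DR(V), h_dt))
                self.n_M = float(advance_gating(self.n_M, alpha_M(V), beta_M(V), h_dt))
                self.n_KCa = float(advance_kca_gating(self.n_KCa, Ca, h_dt))
            self.U_inf += h_dt * (self.V - self.U_inf) / p.tau_Uinf
            V_th = p.V_th0 + p.DB_shift / (1.0 + np.exp(-(self.U_inf - p.V_DB) / p.DB_slope))
            if self.frozen_left <= 0.0 and self.V >= V_th:
                self.spike_times.append(t_ms)
                emitted = self.OVERSHOOT
                self.V = p.V_reset
                self.n_DR = p.n_DR_reset
                self.frozen_left = p.dt_AP
        return emitted if emitted is not None else self.V
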
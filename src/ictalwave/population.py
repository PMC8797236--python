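"""Conductance-based refractory density (CBRD) population core.

A population is represented by the probability density rho of neurons
over the time elapsed since their last spike (t*), together with the
membrane voltage and gating variables parameterized by t*. The density
is transported along t* at unit speed (method of characteristics on a
uniform grid with bin width equal to the time step), drained by the
hazard function H, and re-injected at t* = 0 at the firing rate. The
hazard is the sum of a noise-crossing term A and a drift term B that
only acts when the scaled distance to threshold T decreases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfcx

from .params import HazardParams, PopulationParams

SQRT_2_OVER_PI = np.sqrt(2.0 / np.pi)
T_POLY_CLAMP = -2.5  # validity edge of the published A-term fit


@dataclass
class PopulationState:
    """Density and per-t*-bin neuronal state of one population.

    Bin i covers t* in [i dt, (i+1) dt); ``rho`` stores bin masses (so
    the density value is rho/dt and the masses sum to one). The last bin
    is absorbing: it accumulates all neurons older than the grid and is
    treated as quasi-stationary.
    """

    rho: np.ndarray          # bin masses, sum ~ 1
    U: np.ndarray            # mV
    n_DR: np.ndarray
    n_M: np.ndarray
    n_KCa: np.ndarray
    U_inf: np.ndarray        # low-pass voltage for the dynamic threshold
    T_prev: np.ndarray       # previous scaled distance-to-threshold
    kind: str = "E"

    @classmethod
    def resting(cls, n_bins, V_rest, kind="E"):
        from . import currents as cur
        rho = np.zeros(n_bins)
        rho[-1] = 1.0
        U = np.full(n_bins, float(V_rest))
        n_DR = np.full(n_bins, float(cur.alpha_DR(V_rest)
                                     / (cur.alpha_DR(V_rest) + cur.beta_DR(V_rest))))
        n_M = np.full(n_bins, float(cur.alpha_M(V_rest)
                                    / (cur.alpha_M(V_rest) + cur.beta_M(V_rest))))
        n_KCa = np.zeros(n_bins)
        U_inf = U.copy()
        T_prev = np.full(n_bins, 10.0)
        return cls(rho=rho, U=U, n_DR=n_DR, n_M=n_M, n_KCa=n_KCa,
                   U_inf=U_inf, T_prev=T_prev, kind=kind)

    def total_mass(self) -> float:
        return float(self.rho.sum())


def scaled_threshold_distance(U, V_th, g_syn, g_tot, params: HazardParams):
    """T — the distance to threshold in units of the voltage noise.

    T = (V_th - U) / (sqrt(2) sigma_V), with the noise amplitude growing
    with the synaptic drive: sigma_V = sigma_V0 sqrt(1 + g_syn/g_L) by
    default (a config switch selects the linear scaling
    sigma_V0 (1 + g_syn/g_L)).
    """
    if params.sigma_v_linear:
        sigma_V = params.sigma_V0 * (1.0 + np.asarray(g_syn, float) / params.g_L)
    else:
        sigma_V = params.sigma_V0 * np.sqrt(1.0 + np.asarray(g_syn, float) / params.g_L)
    if params.sigma_ou_current > 0.0:
        # voltage dispersion of the OU bombardment current after membrane
        # filtering: (sigma_I/g_tot) sqrt(tau_N/(tau_N + tau_m))
        g_tot = np.asarray(g_tot, float)
        tau_m = params.C / g_tot
        s_ou = (params.sigma_ou_current / g_tot) \
            * np.sqrt(params.tau_noise / (params.tau_noise + tau_m))
        sigma_V = np.sqrt(sigma_V**2 + s_ou**2)
    return (np.asarray(V_th, float) - np.asarray(U, float)) \
        / (np.sqrt(2.0) * sigma_V)


def hazard_A(T, g_tot, params: HazardParams):
    """Noise-crossing hazard term, 1/ms.

    (1/tau_m) exp(0.0061 - 1.12 T - 0.257 T^2 - 0.072 T^3 - 0.0117 T^4)
    * (1 - (1+k)^(-0.71 + 0.0825 (T+3))), with tau_m = C/g_tot and
    k = tau_m/tau_noise. The polynomial argument is clamped below
    T_POLY_CLAMP where the published fit loses validity (B dominates
    there anyway).
    """
    g_tot = np.asarray(g_tot, float)
    if np.any(~np.isfinite(g_tot)) or np.any(g_tot <= 0):
        raise FloatingPointError("invalid total conductance in hazard")
    tau_m = params.C / g_tot
    k = tau_m / params.tau_noise
    Tc = np.maximum(np.asarray(T, float), T_POLY_CLAMP)
    poly = 0.0061 - 1.12 * Tc - 0.257 * Tc**2 - 0.072 * Tc**3 - 0.0117 * Tc**4
    corr = 1.0 - (1.0 + k) ** (-0.71 + 0.0825 * (Tc + 3.0))
    return np.exp(poly) * np.maximum(corr, 0.0) / tau_m


def hazard_B(T, dT_dt):
    """Drift hazard term, 1/ms.

    2 [-dT/dt]_+ sqrt(2/pi) exp(-T^2)/(1 + erf(T)); evaluated through
    erfcx for numerical stability at strongly suprathreshold T < 0.
    """
    T = np.asarray(T, float)
    drift = np.maximum(-np.asarray(dT_dt, float), 0.0)
    # exp(-T^2)/(1+erf(T)) = 1/erfcx(-T)
    return 2.0 * SQRT_2_OVER_PI * drift / erfcx(-T)


def hazard(U, g_tot, g_syn, V_th, dT_dt, params: HazardParams, T_out=None):
    """Total hazard H = A + B >= 0 (1/ms) for per-bin states.

    Raises on non-finite voltage or nonpositive total conductance.
    """
    U = np.asarray(U, float)
    if np.any(~np.isfinite(U)):
        raise FloatingPointError("non-finite voltage in hazard")
    T = scaled_threshold_distance(U, V_th, g_syn, g_tot, params)
    if T_out is not None:
        T_out[...] = T
    return hazard_A(T, g_tot, params) + hazard_B(T, dT_dt)


def advance_density(rho, H, dt):
    """Transport the density one bin along t* with the hazard sink.

    Returns (rho_shifted, fired_mass). Each bin loses the fraction
    1 - exp(-H dt) to firing; the survivors move one bin to the right,
    with the last (absorbing) bin accumulating. The fired mass is what
    ``apply_spike_boundary`` re-injects at t* = 0, so total mass is
    conserved exactly.
    """
    rho = np.asarray(rho, float)
    surv = rho * np.exp(-np.asarray(H, float) * dt)
    fired = float(rho.sum() - surv.sum())
    out = np.empty_like(surv)
    out[0] = 0.0
    out[1:] = surv[:-1]
    out[-1] += surv[-1]
    return out, fired


def transport_step(state: PopulationState, H, dt):
    """Full t*-transport of a population state; returns the fired mass.

    Applies the hazard sink, shifts the density and every per-bin state
    array one bin along t*, and merges the oldest cohort into the
    absorbing last bin by a survivor-mass-weighted average so that the
    quasi-stationary old-age state is preserved.
    """
    rho = state.rho
    surv = rho * np.exp(-np.asarray(H, float) * dt)
    fired = float(rho.sum() - surv.sum())
    w_old = surv[-1]
    w_new = surv[-2]
    w_sum = w_old + w_new
    for arr in (state.U, state.n_DR, state.n_M, state.n_KCa,
                state.U_inf, state.T_prev):
        if w_sum > 0.0:
            merged = (w_old * arr[-1] + w_new * arr[-2]) / w_sum
        else:
            merged = arr[-1]
        arr[1:] = arr[:-1]
        arr[-1] = merged
    state.rho[0] = 0.0
    state.rho[1:] = surv[:-1]
    state.rho[-1] += w_old
    return fired


def firing_rate(rho, H, dt):
    """Population firing rate nu (1/ms): the integral of rho H over t*.

    Computed as the exactly-conserved per-step fired mass divided by dt,
    which converges to sum(rho H dt*) as dt -> 0.
    """
    rho = np.asarray(rho, float)
    fired = rho.sum() - (rho * np.exp(-np.asarray(H, float) * dt)).sum()
    return float(fired) / dt


def spike_release_peak(rho, H):
    """Index of the peak of the spike-release distribution rho*H."""
    return int(np.argmax(np.asarray(rho, float) * np.asarray(H, float)))


def apply_spike_boundary(state: PopulationState, fired_mass, t_peak_idx,
                         params: PopulationParams, n_frozen):
    """Inject fired mass at t* = 0 and hold the spike-window reset values.

    Within 0 < t* < dt_AP the voltage is clamped to V_reset and the
    fast delayed-rectifier gate to its published reset value 0.5; the slow
    gates (M and K-Ca) are set to their values at the peak of the
    spike-release distribution, carrying the adaptation state across the
    spike.
    """
    state.rho[0] = fired_mass
    nf = n_frozen
    state.U[:nf] = params.V_reset
    state.n_DR[:nf] = params.n_DR_reset
    if fired_mass > 0.0:
        state.n_M[0] = state.n_M[t_peak_idx]
        state.n_KCa[0] = state.n_KCa[t_peak_idx]
    state.T_prev[:nf] = 10.0
    return state


def update_dynamic_threshold(U_inf, U, dt, params: PopulationParams):
    """Relax U_inf toward U (tau = 100 ms) and return (U_inf', V_th).

    V_th = V_th0 + 100 mV * Sigmoid((U_inf - V_DB)/7 mV) raises the
    threshold when the low-passed voltage approaches the depolarization-
    block voltage V_DB = -40 mV, silencing strongly depolarized neurons.
    """
    U_inf = np.asarray(U_inf, float)
    f = np.exp(-dt / params.tau_Uinf)
    U_inf_new = np.asarray(U, float) + (U_inf - np.asarray(U, float)) * f
    V_th = params.V_th0 + params.DB_shift / (
        1.0 + np.exp(-(U_inf_new - params.V_DB) / params.DB_slope))
    return U_inf_new, V_th
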
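"""AMPA/NMDA/GABA conductance kinetics and short-term depression.

Each (synapse type, target population) channel carries a dimensionless
activation m obeying a damped second-order ODE driven by the presynaptic
rate, normalized so that the peak response to an impulse is independent
of the rise/decay time constants. Glutamatergic and GABAergic resources
deplete with use and recover on a 500 ms time scale (Tsodyks-Markram
depression).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .params import SynapseParams, SynapsesParams

_EQ_TC_RTOL = 1e-9


def tau_s(tau_r, tau_d):
    """Normalization time of the second-order synapse.

    (tau_r - tau_d) / ((tau_d/tau_r)^(tau_d/(tau_r-tau_d))
                       - (tau_d/tau_r)^(tau_r/(tau_r-tau_d)))
    with the equal-time-constant limit tau_r * e. Makes the peak
    conductance after a rate impulse independent of (tau_r, tau_d).
    """
    if abs(tau_r - tau_d) <= _EQ_TC_RTOL * max(tau_r, tau_d):
        return tau_r * np.e
    q = tau_d / tau_r
    d = tau_r - tau_d
    return (tau_r - tau_d) / (q ** (tau_d / d) - q ** (tau_r / d))


def nmda_block(V, Mg):
    """Magnesium block factor of the NMDA conductance, in (0, 1].

    1 / (1 + (Mg/3.57) exp(-0.062 V)); Mg in mM, V in mV.
    """
    if np.any(np.asarray(Mg) < 0):
        raise ValueError("Mg must be nonnegative")
    return 1.0 / (1.0 + (Mg / 3.57) * np.exp(-0.062 * np.asarray(V, float)))


def homogeneous_propagator(p: SynapseParams, dt):
    """Exact matrix exponential of the drive-free synapse dynamics.

    The state is (m, m_dot) with
    tau_r tau_d m'' + (tau_r + tau_d) m' + m = 0; the 2x2 propagator is
    precomputed once per synapse type and reused every step.
    """
    a = np.array([[0.0, 1.0],
                  [-1.0 / (p.tau_r * p.tau_d),
                   -(p.tau_r + p.tau_d) / (p.tau_r * p.tau_d)]])
    return expm(a * dt)


def advance_synapse(m, m_dot, phi, p: SynapseParams, dt, propagator=None):
    """One step of the second-order synapse ODE.

    tau_r tau_d m'' + (tau_r+tau_d) m' + m = tau_s (1 - m) phi

    Split into the exact homogeneous propagator plus a first-order
    source impulse (the saturation factor (1-m) is held over the step),
    which is stable for any dt even with sub-dt rise times.
    """
    if propagator is None:
        propagator = homogeneous_propagator(p, dt)
    m = np.asarray(m, float)
    m_dot = np.asarray(m_dot, float)
    src = tau_s(p.tau_r, p.tau_d) * (1.0 - m) * np.asarray(phi, float) \
        / (p.tau_r * p.tau_d)
    m_new = propagator[0, 0] * m + propagator[0, 1] * m_dot
    md_new = propagator[1, 0] * m + propagator[1, 1] * m_dot + src * dt
    return np.maximum(m_new, 0.0), md_new


def conductances(m_ampa, m_nmda, m_gaba, x_glu, x_gaba, V_post,
                 params: SynapsesParams, target, g_ampa_max=None):
    """Effective (g_AMPA, g_NMDA, g_GABA) in mS/cm^2 at the target.

    g_AMPA = g_max m x_glu; g_NMDA = g_max f_NMDA(V) m x_glu;
    g_GABA = g_max m x_gaba. ``g_ampa_max`` overrides the AMPA ceiling
    (used for the spatial gradient onto E cells).
    """
    pa = params.AMPA_E if target == "E" else params.AMPA_I
    pn = params.NMDA_E if target == "E" else params.NMDA_I
    pg = params.GABA_E if target == "E" else params.GABA_I
    ga = (pa.g_max if g_ampa_max is None else g_ampa_max)
    g_AMPA = ga * np.asarray(m_ampa, float) * x_glu
    g_NMDA = pn.g_max * nmda_block(V_post, params.Mg) \
        * np.asarray(m_nmda, float) * x_glu
    g_GABA = pg.g_max * np.asarray(m_gaba, float) * x_gaba
    return g_AMPA, g_NMDA, g_GABA


def advance_depression(x, phi, u, tau, dt):
    """Tsodyks-Markram resource update: dx/dt = (1-x)/tau - u x phi.

    Exponential-Euler (exact for constant phi); x stays in [0, 1] for
    nonnegative inputs. u = 0 disables depression.
    """
    x = np.asarray(x, float)
    phi = np.asarray(phi, float)
    rate = 1.0 / tau + u * phi
    x_inf = (1.0 / tau) / rate
    return x_inf + (x - x_inf) * np.exp(-rate * dt)


def depression_steady_state(phi, u, tau):
    """Fixed point x* = 1 / (1 + u tau phi) under a constant rate."""
    return 1.0 / (1.0 + u * tau * np.asarray(phi, float))
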
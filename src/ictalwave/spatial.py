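"""1-D spatial structure: connection kernel, diffusion, AMPA gradient.

The cortical segment is a uniform grid of length L (default 2.5 mm).
Presynaptic rates are the somatic rates convolved with a Gaussian
connection profile of characteristic length lambda, renormalized per
node over the truncated domain; an optional fraction of the drive is
replaced by the domain-mean rate (all-to-all connections).
Extracellular potassium diffuses with a second-difference Laplacian
under zero-flux boundaries.
"""

from __future__ import annotations

import numpy as np

from .params import SpatialParams


class SpatialGrid:
    """Node positions and virtual-electrode indices of the 1-D segment."""

    def __init__(self, params: SpatialParams):
        self.p = params
        self.x = np.linspace(0.0, params.L, params.n_x)
        self.dx = params.dx
        i1, i2 = (int(round(f * (params.n_x - 1)))
                  for f in params.electrode_fracs)
        if i1 == i2:
            raise ValueError("electrode sites S1 and S2 coincide")
        self.s1, self.s2 = i1, i2

    @property
    def electrode_distance(self) -> float:
        """Distance between the two virtual electrodes, mm."""
        return abs(self.x[self.s2] - self.x[self.s1])


def connection_kernel(grid: SpatialGrid, lam):
    """Row-normalized Gaussian connection matrix W (n_x, n_x).

    phi = W nu implements the ratio-of-integrals convolution: the kernel
    exp(-(x-x')^2/lambda^2) is truncated at the domain boundaries and
    renormalized per node, so each row sums to one and a spatially
    uniform rate is mapped onto itself. lambda = 0 degenerates to the
    identity (purely local drive).
    """
    n = grid.p.n_x
    if lam <= 0.0:
        return np.eye(n)
    d = grid.x[:, None] - grid.x[None, :]
    W = np.exp(-(d / lam) ** 2)
    W /= W.sum(axis=1, keepdims=True)
    return W


def presynaptic_rate_field(nu_field, W):
    """phi(x) = sum_x' W[x, x'] nu(x')."""
    return W @ np.asarray(nu_field, float)


def mix_long_range(phi_field, nu_field, fraction):
    """Blend a fraction of all-to-all (domain-mean) drive into phi."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("all-to-all fraction must be within [0, 1]")
    if fraction == 0.0:
        return np.asarray(phi_field, float)
    return (1.0 - fraction) * np.asarray(phi_field, float) \
        + fraction * float(np.mean(nu_field))


def diffusion_operator(field, D, dx):
    """D * second-difference Laplacian with zero-flux (Neumann) ends.

    Returns the rate field D d^2 f/dx^2 (units of f per ms). Neumann
    boundaries mirror the edge nodes, so a uniform field and the
    interior of a linear ramp map to zero and the v-weighted total is
    conserved.
    """
    f = np.asarray(field, float)
    lap = np.empty_like(f)
    lap[1:-1] = f[2:] - 2.0 * f[1:-1] + f[:-2]
    lap[0] = f[1] - f[0]
    lap[-1] = f[-2] - f[-1]
    return D * lap / dx**2


def ampa_gradient_profile(grid: SpatialGrid, g_max, enabled=True):
    """Linear max-AMPA-onto-E profile: 0 at x = 0, g_max at x = L."""
    if g_max < 0:
        raise ValueError("g_max must be nonnegative")
    if not enabled:
        return np.full(grid.p.n_x, float(g_max))
    return g_max * grid.x / grid.p.L
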
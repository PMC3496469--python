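"""Model parameters, voltage grids, coefficient functions and initial densities.

The nonlinear noisy leaky integrate-and-fire (NNLIF) population model tracks
the probability density ``p(v, t)`` of membrane potentials of a large,
sparsely coupled network of neurons.  In the reduced voltage variables the
Fokker-Planck equation reads

    dp/dt + d/dv[ h(v, N) p ] - a(N) d2p/dv2 = N(t) * delta(v - V_R),

on ``v in (-inf, V_F]``, with absorbing (Dirichlet) boundary ``p(V_F) = 0``
and the mean firing rate ``N(t) = -a(N) dp/dv`` evaluated at ``V_F``.  The
drift and diffusion are

    h(v, N) = b*N - v,        a(N) = a0 + a1*N,

where ``b`` is the mean network connectivity (``b > 0`` excitatory-average,
``b < 0`` inhibitory-average), ``a0 > 0`` the baseline noise and ``a1 >= 0``
the firing-rate-dependent noise gain.  Every neuron that reaches the firing
threshold ``V_F`` is instantaneously reset to ``V_R``, which is the Dirac
source on the right-hand side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("nnlif")

__all__ = [
    "ModelParams",
    "Grid",
    "DensityState",
    "drift",
    "diffusion",
    "make_grid",
    "default_v_min",
    "maxwellian_density",
]


@dataclass(frozen=True)
class ModelParams:
    """Coefficient set of the NNLIF drift/diffusion pair.

    Parameters
    ----------
    b : float
        Connectivity (dimensionless voltage units). Sign selects an
        excitatory- (``b > 0``) or inhibitory-average (``b < 0``) network.
    a0 : float
        Baseline diffusion coefficient, strictly positive.
    a1 : float
        Firing-rate diffusion gain, non-negative.
    v_reset : float
        Reset voltage ``V_R``.
    v_thresh : float
        Firing threshold voltage ``V_F``; must exceed ``v_reset``.
    """

    b: float
    a0: float = 1.0
    a1: float = 0.0
    v_reset: float = 1.0
    v_thresh: float = 2.0

    def __post_init__(self) -> None:
        if not self.v_reset < self.v_thresh:
            raise ValueError(
                f"require V_R < V_F, got V_R={self.v_reset}, V_F={self.v_thresh}"
            )
        if not self.a0 > 0:
            raise ValueError(f"baseline diffusion a0 must be > 0, got {self.a0}")
        if self.a1 < 0:
            raise ValueError(f"diffusion gain a1 must be >= 0, got {self.a1}")


def drift(v, N: float, params: ModelParams):
    """Drift velocity ``h(v, N) = b*N - v`` (leak plus mean synaptic input)."""
    return params.b * N - np.asarray(v) if np.ndim(v) else params.b * N - v


def diffusion(N: float, params: ModelParams) -> float:
    """Diffusion coefficient ``a(N) = a0 + a1*N``; strictly positive for N >= 0."""
    return params.a0 + params.a1 * N


@dataclass(frozen=True)
class Grid:
    """Uniform voltage mesh on ``[V_min, V_F]`` with ``V_R`` and ``V_F`` on nodes.

    ``nodes[idx_reset]`` is exactly ``V_R``: the reset source deposits mass
    on a single node, which reproduces the derivative jump of the stationary
    profile at ``V_R``.
    """

    v_min: float
    v_thresh: float
    n_nodes: int
    dv: float
    idx_reset: int
    nodes: np.ndarray = field(repr=False)

    def trapz(self, f: np.ndarray) -> float:
        """Trapezoidal quadrature of nodal values over the grid."""
        return float(np.trapezoid(f, dx=self.dv))


def make_grid(v_min: float, params: ModelParams, n_nodes: int) -> Grid:
    """Build a uniform grid whose node set contains ``V_R`` and ``V_F`` exactly.

    The spacing implied by the request, ``dv0 = (V_F - v_min)/(n_nodes - 1)``,
    rarely divides ``V_F - V_R`` evenly.  The spacing is therefore snapped to
    ``(V_F - V_R)/m`` with ``m = round((V_F - V_R)/dv0)`` and, if the snapped
    mesh no longer covers the requested ``v_min``, nodes are appended below
    (a shift of less than one cell).  The adjustment is logged.
    """
    vr, vf = params.v_reset, params.v_thresh
    if n_nodes < 16:
        raise ValueError(f"grid needs at least 16 nodes, got {n_nodes}")
    if not v_min < vr:
        raise ValueError(f"require V_min < V_R, got V_min={v_min}, V_R={vr}")

    dv0 = (vf - v_min) / (n_nodes - 1)
    m_above = max(1, round((vf - vr) / dv0))
    dv = (vf - vr) / m_above
    n = n_nodes
    grid_v_min = vf - (n - 1) * dv
    if grid_v_min > v_min + 1e-12 * dv:
        extra = math.ceil((grid_v_min - v_min) / dv - 1e-12)
        n += extra
        grid_v_min = vf - (n - 1) * dv
    if abs(grid_v_min - v_min) > 1e-12 * max(1.0, abs(v_min)):
        logger.info(
            "grid aligned to put V_R on a node: V_min %.6g -> %.6g (dv=%.6g, J=%d)",
            v_min, grid_v_min, dv, n,
        )
    nodes = vf + dv * np.arange(-(n - 1), 1, dtype=float)
    idx_reset = n - 1 - m_above
    # exactness of the special nodes matters for the reset deposition
    nodes[idx_reset] = vr
    nodes[-1] = vf
    return Grid(
        v_min=float(nodes[0]), v_thresh=vf, n_nodes=n, dv=dv,
        idx_reset=idx_reset, nodes=nodes,
    )


def default_v_min(params: ModelParams, v0: float | None = None,
                  sigma2: float | None = None) -> float:
    """Lower cutoff placing the truncation where the density is negligible.

    The solution decays like a Gaussian of variance ``a(N)`` centred at
    ``b*N``; eight standard deviations below the reset keep the truncated
    tail (and hence the flux leaking through ``V_min``) far below the mass
    conservation tolerance of the solver.  When a Gaussian initial datum is
    given, its own eight-sigma tail is honoured as well.
    """
    v_min = params.v_reset - 8.0 * math.sqrt(params.a0)
    if params.b < 0:
        # inhibitory drift pushes the bulk to V0 = b*N < 0; allow room
        v_min = min(v_min, params.b * 1.0 - 8.0 * math.sqrt(params.a0))
    if v0 is not None and sigma2 is not None:
        v_min = min(v_min, v0 - 8.0 * math.sqrt(sigma2))
    return v_min


@dataclass
class DensityState:
    """Density values on a grid at time ``t`` with the current firing rate.

    Invariants: ``p >= 0`` everywhere, ``p`` vanishes at the threshold node,
    and the trapezoidal integral of ``p`` equals one (the solver keeps it
    there to rounding).
    """

    grid: Grid
    p: np.ndarray
    t: float = 0.0
    N: float = 0.0

    @property
    def mass(self) -> float:
        return self.grid.trapz(self.p)

    def copy(self) -> "DensityState":
        return DensityState(self.grid, self.p.copy(), self.t, self.N)


def _normalize(grid: Grid, p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, None)
    p[-1] = 0.0
    mass = grid.trapz(p)
    if mass <= 0:
        raise ValueError("density has no mass on the grid")
    return p / mass


def maxwellian_density(grid: Grid, v0: float, sigma2: float,
                       params: ModelParams | None = None) -> DensityState:
    """Gaussian initial datum of mean ``v0`` and variance ``sigma2``.

    The Gaussian is evaluated on the nodes, forced to zero at ``V_F`` and
    renormalized to unit trapezoidal mass (the model evolves probability
    densities, so truncation mass is put back by rescaling).  A warning is
    emitted when more than 1% of the untruncated mass falls outside the
    grid, meaning the grid is too small for this initial datum.
    """
    if sigma2 <= 0:
        raise ValueError(f"variance must be positive, got {sigma2}")
    sig = math.sqrt(sigma2)
    from scipy.stats import norm

    inside = norm.cdf(grid.v_thresh, v0, sig) - norm.cdf(grid.v_min, v0, sig)
    if inside < 0.99:
        logger.warning(
            "%.2f%% of the Gaussian(v0=%g, sigma2=%g) mass lies outside "
            "[%g, %g]; the grid is too small for this initial datum",
            100 * (1 - inside), v0, sigma2, grid.v_min, grid.v_thresh,
        )
    p = np.exp(-0.5 * ((grid.nodes - v0) / sig) ** 2) / (sig * math.sqrt(2 * math.pi))
    p = _normalize(grid, p)
    state = DensityState(grid, p, t=0.0, N=0.0)
    if params is not None:
        from .pde_solver import firing_rate_from_density

        state.N = firing_rate_from_density(state, params)
    return state
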
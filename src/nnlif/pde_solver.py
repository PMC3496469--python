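"""Explicit finite-difference solvers for the NNLIF Fokker-Planck equation.

Two spatial discretizations are provided on the uniform voltage grid, both
assembled from interface fluxes ``Phi_{i+1/2}`` so that the discrete mass
budget closes exactly:

* ``upwind1`` / ``weno5`` - the advective flux ``h p`` is upwinded by the
  sign of the drift (first order, or with fifth-order WENO reconstruction of
  the Lax-Friedrichs-split flux), the diffusion ``a p_vv`` uses second-order
  centred differences.
* ``chang_cooper`` - the equation is written in Maxwellian flux form
  ``a d/dv[M d/dv(p/M)]`` with ``M = exp(-(v-bN)^2/(2a))`` and discretized
  with exponential-fitting interface weights, which preserves positivity
  and is exact on the local Maxwellian.

Time stepping is strong-stability-preserving (TVD) Runge-Kutta of order 2
or 3 with the firing rate re-evaluated from the stage density at every
stage.  The mass that crosses the threshold interface each step is
re-deposited on the reset node, so total mass is conserved to rounding; the
lower cut-off ``V_min`` is treated as a zero-flux wall in a region where
the density is required to stay below a leak guard.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model_core import DensityState, Grid, ModelParams

logger = logging.getLogger("nnlif")

__all__ = [
    "SchemeConfig",
    "SolverResult",
    "FiringRateBreakdown",
    "chang_cooper_delta",
    "firing_rate_from_density",
    "step_upwind",
    "step_chang_cooper",
    "run_simulation",
]

_SCHEMES = {"upwind1": 0, "weno5": 1, "chang_cooper": 2}


def chang_cooper_delta(w: float) -> float:
    """Chang-Cooper interface weight ``delta(w) = 1/w - 1/(e^w - 1)``.

    ``w`` is the cell Peclet number of the Maxwellian flux form.  The weight
    interpolates between centred differencing (``delta -> 1/2`` as
    ``w -> 0``) and full upwinding (``delta -> 0`` or ``1`` as
    ``w -> +/-inf``), and is the unique choice that zeroes the discrete
    flux on the local Maxwellian sampled at the nodes.
    """
    if abs(w) < 1e-8:
        return 0.5 - w / 12.0
    return 1.0 / w - 1.0 / math.expm1(w)


class FiringRateBreakdown(RuntimeError):
    """The implicit relation N = a(N) q has lost its unique solution.

    With ``a(N) = a0 + a1 N`` the firing-rate definition becomes
    ``N = a0 q / (1 - a1 q)``; once ``a1 q >= 1`` no non-negative solution
    exists.  This is the blow-up scenario of the rate-dependent-noise model:
    the firing rate diverges even though the boundary derivative does not.
    """


@dataclass
class SchemeConfig:
    """Scheme and run configuration.

    ``N_blowup=None`` selects a grid-aware threshold for excitatory
    networks: the stationary threshold boundary layer has width
    ``a/(b N - V_F)``, so once ``b N - V_F > a/dv`` the layer is thinner
    than one cell and the computation has left the resolvable regime; the
    run is then terminated with ``status='blowup'``.  (For ``b <= 0`` a
    fixed fallback of 1e3 applies; such runs never approach it.)
    """

    scheme: str = "weno5"
    cfl: float = 0.5
    rk_order: int = 2
    t_end: float = 10.0
    snapshot_times: tuple[float, ...] = ()
    N_blowup: float | None = None
    steady_tol: float = 1e-6
    check_interval: float = 0.05
    vmin_leak_tol: float = 1e-6
    entropy_ref: DensityState | None = None

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; "
                             f"choose from {sorted(_SCHEMES)}")
        if not 0 < self.cfl <= 1:
            raise ValueError("cfl must lie in (0, 1]")
        if self.rk_order not in (2, 3):
            raise ValueError("rk_order must be 2 or 3")
        if self.steady_tol <= 0 or (self.N_blowup is not None and self.N_blowup <= 0):
            raise ValueError("steady_tol and N_blowup must be positive")


@dataclass
class SolverResult:
    """Per-step traces, snapshots and the termination status of a run."""

    times: np.ndarray
    N_trace: np.ndarray
    mass_trace: np.ndarray
    m1_trace: np.ndarray          # int (V_F - v) p dv
    m2_trace: np.ndarray          # int v^2 p dv
    entropy_trace: np.ndarray | None
    snapshots: list[DensityState]
    final: DensityState
    status: str
    status_time: float
    clipped_mass: float
    params: ModelParams
    config: SchemeConfig
    N_threshold: float = math.nan


def firing_rate_from_density(state: DensityState, params: ModelParams) -> float:
    """Firing rate from the boundary derivative, N = -a(N) dp/dv at V_F.

    The derivative is the second-order one-sided stencil through the
    Dirichlet zero at the threshold node; negative stencil values (possible
    for rough data) are clamped to zero.  For ``a1 > 0`` the implicit
    relation is solved in closed form and :class:`FiringRateBreakdown` is
    raised when it has no solution.
    """
    p, dv = state.p, state.grid.dv
    q = (4.0 * p[-2] - p[-3]) / (2.0 * dv)
    q = max(q, 0.0)
    if params.a1 > 0 and params.a1 * q >= 1.0:
        raise FiringRateBreakdown(
            f"a1*|dp/dv|(V_F) = {params.a1 * q:.4g} >= 1: the implicit "
            "firing-rate relation has no solution")
    return params.a0 * q / (1.0 - params.a1 * q)


# ---------------------------------------------------------------------------
# jitted kernels: interface fluxes and stage updates
# ---------------------------------------------------------------------------

@njit(cache=True)
def _stencil_q(p, dv):
    q = (4.0 * p[-2] - p[-3]) / (2.0 * dv)
    return q if q > 0.0 else 0.0


@njit(cache=True)
def _rate(q, a0, a1):
    # returns (N, ok); ok=False when the implicit relation breaks down
    if a1 > 0.0 and a1 * q >= 1.0:
        return 0.0, False
    return a0 * q / (1.0 - a1 * q), True


@njit(cache=True)
def _weno_rec(fm2, fm1, f0, fp1, fp2):
    # fifth-order WENO reconstruction at the right cell edge (left-biased)
    eps = 1e-6
    b0 = 13.0 / 12.0 * (fm2 - 2.0 * fm1 + f0) ** 2 + 0.25 * (fm2 - 4.0 * fm1 + 3.0 * f0) ** 2
    b1 = 13.0 / 12.0 * (fm1 - 2.0 * f0 + fp1) ** 2 + 0.25 * (fm1 - fp1) ** 2
    b2 = 13.0 / 12.0 * (f0 - 2.0 * fp1 + fp2) ** 2 + 0.25 * (3.0 * f0 - 4.0 * fp1 + fp2) ** 2
    a0 = 0.1 / (eps + b0) ** 2
    a1 = 0.6 / (eps + b1) ** 2
    a2 = 0.3 / (eps + b2) ** 2
    q0 = (2.0 * fm2 - 7.0 * fm1 + 11.0 * f0) / 6.0
    q1 = (-fm1 + 5.0 * f0 + 2.0 * fp1) / 6.0
    q2 = (2.0 * f0 + 5.0 * fp1 - fp2) / 6.0
    return (a0 * q0 + a1 * q1 + a2 * q2) / (a0 + a1 + a2)


@njit(cache=True)
def _fluxes(scheme, p, v, dv, b, N, a):
    """Total interface fluxes Phi_{i+1/2} = (h p)_{i+1/2} - a (dp/dv)_{i+1/2}.

    Phi[i] sits between nodes i and i+1; Phi[0] (the V_min wall) is zeroed
    by the caller.  Ghost values of p beyond both ends are zero: the density
    is negligible at V_min and identically zero above threshold.
    """
    J = p.shape[0]
    phi = np.empty(J - 1)
    if scheme == 0:  # first-order upwind advection
        for i in range(J - 1):
            hm = b * N - 0.5 * (v[i] + v[i + 1])
            adv = hm * p[i] if hm > 0.0 else hm * p[i + 1]
            phi[i] = adv - a * (p[i + 1] - p[i]) / dv
    elif scheme == 1:  # WENO5 with stencil-local Lax-Friedrichs splitting
        # densities and drifts with two ghost nodes each side (p=0 outside)
        pe = np.zeros(J + 4)
        he = np.empty(J + 4)
        for j in range(J + 4):
            he[j] = b * N - (v[0] + (j - 2) * dv)
            if 2 <= j < J + 2:
                pe[j] = p[j - 2]
        for i in range(J - 1):
            g = i + 2
            alpha = 0.0
            for k in range(g - 2, g + 4):
                if abs(he[k]) > alpha:
                    alpha = abs(he[k])
            adv = (_weno_rec(
                0.5 * (he[g - 2] + alpha) * pe[g - 2],
                0.5 * (he[g - 1] + alpha) * pe[g - 1],
                0.5 * (he[g] + alpha) * pe[g],
                0.5 * (he[g + 1] + alpha) * pe[g + 1],
                0.5 * (he[g + 2] + alpha) * pe[g + 2])
                + _weno_rec(
                0.5 * (he[g + 3] - alpha) * pe[g + 3],
                0.5 * (he[g + 2] - alpha) * pe[g + 2],
                0.5 * (he[g + 1] - alpha) * pe[g + 1],
                0.5 * (he[g] - alpha) * pe[g],
                0.5 * (he[g - 1] - alpha) * pe[g - 1]))
            phi[i] = adv - a * (p[i + 1] - p[i]) / dv
    else:  # Chang-Cooper exponential fitting
        for i in range(J - 1):
            hm = b * N - 0.5 * (v[i] + v[i + 1])
            w = -dv * hm / a
            if abs(w) < 1e-8:
                delta = 0.5 - w / 12.0
            else:
                delta = 1.0 / w - 1.0 / math.expm1(w)
            phi[i] = hm * ((1.0 - delta) * p[i + 1] + delta * p[i]) \
                - a * (p[i + 1] - p[i]) / dv
    phi[0] = 0.0
    return phi


@njit(cache=True)
def _stage(scheme, p, v, dv, i_reset, b, a0, a1):
    """One Euler stage dp = L(p); returns (dp, N, ok).

    The flux through the last interface (just below V_F) is re-deposited on
    the reset node, closing the mass budget exactly.
    """
    q = _stencil_q(p, dv)
    N, ok = _rate(q, a0, a1)
    if not ok:
        return np.zeros_like(p), 0.0, False
    a = a0 + a1 * N
    phi = _fluxes(scheme, p, v, dv, b, N, a)
    J = p.shape[0]
    dp = np.zeros(J)
    for i in range(1, J - 1):
        dp[i] = -(phi[i] - phi[i - 1]) / dv
    dp[i_reset] += phi[J - 2] / dv
    return dp, N, ok


@njit(cache=True)
def _clip_negatives(p, dv):
    clipped = 0.0
    for i in range(p.shape[0]):
        if p[i] < 0.0:
            clipped -= p[i] * dv
            p[i] = 0.0
    p[0] = 0.0
    p[-1] = 0.0
    return clipped


@njit(cache=True)
def _rk_step(scheme, rk_order, p, v, dv, i_reset, b, a0, a1, dt):
    """One SSP-RK step. Returns (p_new, N_start, clipped_mass, ok)."""
    k1, N0, ok = _stage(scheme, p, v, dv, i_reset, b, a0, a1)
    if not ok:
        return p, 0.0, 0.0, False
    clipped = 0.0
    p1 = p + dt * k1
    clipped += _clip_negatives(p1, dv)
    k2, _, ok = _stage(scheme, p1, v, dv, i_reset, b, a0, a1)
    if not ok:
        return p, N0, clipped, False
    if rk_order == 2:
        pn = 0.5 * (p + p1 + dt * k2)
        clipped += _clip_negatives(pn, dv)
        return pn, N0, clipped, True
    p2 = 0.75 * p + 0.25 * (p1 + dt * k2)
    clipped += _clip_negatives(p2, dv)
    k3, _, ok = _stage(scheme, p2, v, dv, i_reset, b, a0, a1)
    if not ok:
        return p, N0, clipped, False
    pn = p / 3.0 + 2.0 / 3.0 * (p2 + dt * k3)
    clipped += _clip_negatives(pn, dv)
    return pn, N0, clipped, True


# ---------------------------------------------------------------------------
# single-step wrappers and the simulation driver
# ---------------------------------------------------------------------------

def _cfl_dt(config: SchemeConfig, grid: Grid, params: ModelParams, N: float) -> float:
    a = params.a0 + params.a1 * N
    hmax = max(abs(params.b * N - grid.v_min),
               abs(params.b * N - grid.v_thresh))
    return config.cfl * min(grid.dv / max(hmax, 1e-300),
                            grid.dv * grid.dv / (2.0 * a))


def _one_step(state: DensityState, params: ModelParams, dt: float,
              scheme: str, rk_order: int = 2,
              cfl_check: bool = True) -> DensityState:
    grid = state.grid
    if cfl_check:
        dt_max = _cfl_dt(SchemeConfig(scheme=scheme, cfl=1.0), grid, params,
                         firing_rate_from_density(state, params))
        if dt > dt_max * (1 + 1e-12):
            raise ValueError(f"dt={dt:g} violates the stability bound {dt_max:g}")
    p_new, _, _, ok = _rk_step(
        _SCHEMES[scheme], rk_order, state.p, grid.nodes, grid.dv,
        grid.idx_reset, params.b, params.a0, params.a1, dt)
    if not ok:
        raise FiringRateBreakdown(
            "firing-rate relation broke down during the step (a1*q >= 1)")
    out = DensityState(grid, p_new, t=state.t + dt, N=0.0)
    out.N = firing_rate_from_density(out, params)
    return out


def step_upwind(state: DensityState, params: ModelParams, dt: float,
                rk_order: int = 2, weno: bool = False) -> DensityState:
    """Advance one SSP-RK step with upwind (or WENO5) advection."""
    return _one_step(state, params, dt, "weno5" if weno else "upwind1", rk_order)


def step_chang_cooper(state: DensityState, params: ModelParams, dt: float,
                      rk_order: int = 2) -> DensityState:
    """Advance one SSP-RK step with the Chang-Cooper flux discretization."""
    N = firing_rate_from_density(state, params)
    if params.a1 == 0 and params.b > 0 and params.b * N > state.grid.v_thresh + 2.0:
        logger.warning(
            "Chang-Cooper with constant diffusion and large firing rate "
            "(b*N=%.3g): the Maxwellian drift nearly vanishes on the domain; "
            "this is the scheme's known bad regime", params.b * N)
    return _one_step(state, params, dt, "chang_cooper", rk_order)


class _TraceBuffer:
    """Growable per-step trace storage (times, N, mass, moments, entropy)."""

    def __init__(self, ncol: int, cap: int = 1 << 16) -> None:
        self.data = np.empty((cap, ncol))
        self.n = 0

    def append(self, row: tuple) -> None:
        if self.n == self.data.shape[0]:
            self.data = np.vstack([self.data, np.empty_like(self.data)])
        self.data[self.n] = row
        self.n += 1

    def column(self, j: int) -> np.ndarray:
        return self.data[: self.n, j].copy()


def default_blowup_threshold(params: ModelParams, grid: Grid) -> float:
    """Firing rate beyond which the threshold boundary layer is unresolved.

    The stationary profile rises from the Dirichlet zero over a layer of
    width ``a/(b N - V_F)`` (drift against diffusion); requiring at least
    one cell inside the layer gives ``N < (a0/dv + V_F)/b`` for excitatory
    networks.  Beyond it the discrete firing rate saturates at a
    grid-dependent ceiling instead of diverging, so the run is terminated
    and flagged as blow-up.
    """
    if params.b > 0:
        return (params.a0 / grid.dv + params.v_thresh) / params.b
    return 1e3


def run_simulation(params: ModelParams, init: DensityState,
                   config: SchemeConfig) -> SolverResult:
    """Advance the density to ``t_end`` or a terminal status.

    The time step is recomputed every step from the stability bound
    ``dt = cfl * min(dv/max|h|, dv^2/(2a))``.  Statuses:

    * ``steady`` - L1 change per unit time fell below ``steady_tol``;
    * ``blowup`` - firing rate crossed the blow-up threshold, or the time
      step collapsed below ``1e-12 * t_end``;
    * ``cc_breakdown`` - the implicit firing-rate relation lost its
      solution (``a1 q >= 1``, the rate-dependent-noise blow-up);
    * ``vmin_leak`` - the density at the lower cut-off exceeded the leak
      guard, invalidating the truncation;
    * ``reached_t_end`` otherwise.
    """
    grid = init.grid
    scheme = _SCHEMES[config.scheme]
    v, dv, i_reset = grid.nodes, grid.dv, grid.idx_reset
    b, a0, a1 = params.b, params.a0, params.a1
    n_threshold = config.N_blowup if config.N_blowup is not None \
        else default_blowup_threshold(params, grid)

    # trapezoid weights and moment kernels for per-step traces
    wts = np.full(grid.n_nodes, dv)
    wts[0] = wts[-1] = 0.5 * dv
    k_mass = wts
    k_m1 = wts * (grid.v_thresh - v)
    k_m2 = wts * v * v
    ref = config.entropy_ref
    if ref is not None:
        pinf = ref.p
        live = pinf > 1e-30
        inv_pinf = np.where(live, 1.0 / np.where(live, pinf, 1.0), 0.0)
        k_ent = wts * np.where(live, pinf, 0.0)

    def entropy(p: np.ndarray) -> float:
        r = p * inv_pinf - 1.0
        return float(k_ent @ (r * r))

    buf = _TraceBuffer(6 if ref is not None else 5)
    p = init.p.copy()
    t = float(init.t)
    status, status_time = "reached_t_end", t
    clipped_total = 0.0
    snapshots: list[DensityState] = []
    snap_iter = iter(sorted(config.snapshot_times))
    next_snap = next(snap_iter, None)
    last_p, last_t = p.copy(), t
    next_check = t + config.check_interval
    i_guard = 2  # density monitored on the first interior nodes above V_min

    def record(N: float) -> None:
        row = [t, N, k_mass @ p, k_m1 @ p, k_m2 @ p]
        if ref is not None:
            row.append(entropy(p))
        buf.append(tuple(row))

    try:
        N = firing_rate_from_density(DensityState(grid, p), params)
    except FiringRateBreakdown:
        logger.warning("firing-rate relation already broken for the initial "
                       "density (a1 |dp/dv| >= 1 at V_F)")
        return SolverResult(
            times=np.array([t]), N_trace=np.array([math.nan]),
            mass_trace=np.array([k_mass @ p]), m1_trace=np.array([k_m1 @ p]),
            m2_trace=np.array([k_m2 @ p]),
            entropy_trace=np.array([entropy(p)]) if ref is not None else None,
            snapshots=[], final=DensityState(grid, p, t, math.nan),
            status="cc_breakdown", status_time=t, clipped_mass=0.0,
            params=params, config=config, N_threshold=n_threshold)
    record(N)
    warned_cc = False
    while t < config.t_end - 1e-14 * config.t_end:
        if (scheme == 2 and not warned_cc and a1 == 0 and b > 0
                and b * N > grid.v_thresh + 2.0):
            logger.warning(
                "Chang-Cooper with constant diffusion at large firing rate "
                "(b*N=%.3g): the Maxwellian drift nearly vanishes on the "
                "domain; prefer weno5/upwind1 here", b * N)
            warned_cc = True
        dt = _cfl_dt(config, grid, params, N)
        if dt < 1e-12 * config.t_end:
            status, status_time = "blowup", t
            break
        dt = min(dt, config.t_end - t)
        if next_snap is not None and t < next_snap <= t + dt:
            dt = next_snap - t
        p_new, _, clipped, ok = _rk_step(scheme, config.rk_order, p, v, dv,
                                         i_reset, b, a0, a1, dt)
        if not ok:
            status, status_time = "cc_breakdown", t
            break
        p = p_new
        t += dt
        clipped_total += clipped
        q = _stencil_q(p, dv)
        N, ok = _rate(q, a0, a1)
        if not ok:
            status, status_time = "cc_breakdown", t
            break
        record(N)
        if next_snap is not None and t >= next_snap - 1e-12:
            snapshots.append(DensityState(grid, p.copy(), t, N))
            next_snap = next(snap_iter, None)
        if N >= n_threshold:
            status, status_time = "blowup", t
            break
        if t >= next_check:
            if np.max(p[:i_guard + 1]) > config.vmin_leak_tol:
                status, status_time = "vmin_leak", t
                logger.warning("density near V_min exceeded %g at t=%g; "
                               "the domain truncation is no longer valid",
                               config.vmin_leak_tol, t)
                break
            drift = float(np.sum(np.abs(p - last_p))) * dv / (t - last_t)
            if drift < config.steady_tol:
                status, status_time = "steady", t
                break
            last_p, last_t = p.copy(), t
            next_check = t + config.check_interval
    else:
        status_time = t

    final = DensityState(grid, p, t, N)
    if clipped_total > 0:
        logger.info("clipped %.3e of (negative) mass in total", clipped_total)
    return SolverResult(
        times=buf.column(0), N_trace=buf.column(1), mass_trace=buf.column(2),
        m1_trace=buf.column(3), m2_trace=buf.column(4),
        entropy_trace=buf.column(5) if ref is not None else None,
        snapshots=snapshots, final=final, status=status,
        status_time=status_time, clipped_mass=clipped_total,
        params=params, config=config, N_threshold=n_threshold,
    )
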
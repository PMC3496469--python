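"""Blow-up certificates, a-priori moment bounds, and entropy relaxation.

For an excitatory-average network (``b > 0``) a checkable sufficient
condition for finite-time loss of solutions is available: choose a
multiplier exponent ``mu > max(V_F/a_m, 1/b)`` (``a_m`` the diffusion lower
bound, here ``a0``); if the exponential moment of the initial density

    M_mu(0) = int e^{mu v} p0(v) dv

is at least ``lambda = (e^{mu V_F} - e^{mu V_R})/(b mu)``, the weak solution
cannot exist globally in time - numerically the firing rate diverges in
finite time (partial synchronization of the network).

In the uncoupled linear case (``b = 0``, constant diffusion) the dynamics
relax to the unique Dawson-form equilibrium ``p_inf`` and the relative
entropy

    H(t) = int p_inf (p/p_inf - 1)^2 dv

decays monotonically (exponentially, with a rate set by a weighted
Poincare constant that is known to exist but has no printed value; this
module only fits the empirical decay rate).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import DensityState, ModelParams
from .pde_solver import SolverResult

logger = logging.getLogger("nnlif")

__all__ = [
    "BlowupCertificate",
    "EntropyTrace",
    "exponential_moment",
    "blowup_lambda",
    "blowup_certificate",
    "moment_bounds_report",
    "MomentBoundsReport",
    "relative_entropy",
    "relative_entropy_trace",
]

#: far-tail floor for the equilibrium density in entropy quotients; the
#: region it masks carries a vanishing share of the integral.
PINF_FLOOR = 1e-30


def exponential_moment(state: DensityState, mu: float) -> float:
    """Trapezoidal ``int e^{mu v} p dv`` over the grid.

    Computed as ``e^{mu V_F} * int e^{mu (v - V_F)} p dv`` so the working
    exponents are non-positive; only the final scale can saturate, and only
    where the certificate threshold saturates identically.
    """
    if mu <= 0:
        raise ValueError(f"multiplier exponent must be positive, got {mu}")
    g = state.grid
    rel = np.exp(mu * (g.nodes - g.v_thresh))
    return math.exp(mu * g.v_thresh) * g.trapz(rel * state.p)


def blowup_lambda(mu: float, params: ModelParams) -> float:
    """Certificate threshold ``lambda = (e^{mu V_F} - e^{mu V_R})/(b mu)``."""
    if params.b <= 0:
        raise ValueError("the blow-up threshold requires b > 0")
    return (math.exp(mu * params.v_thresh)
            - math.exp(mu * params.v_reset)) / (params.b * mu)


@dataclass(frozen=True)
class BlowupCertificate:
    """Outcome of the exponential-moment blow-up test for one initial datum.

    ``certified`` implies ``b > 0``, an admissible ``mu`` and
    ``M_mu0 >= lambda_thresh``; the converse direction is not asserted (an
    uncertified datum may still blow up).
    """

    mu: float
    lambda_thresh: float
    M_mu0: float
    mu_conditions_ok: bool
    certified: bool
    a_m: float
    reason: str = ""
    scanned_mu: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.certified:
            assert self.mu_conditions_ok and self.M_mu0 >= self.lambda_thresh


def blowup_certificate(init: DensityState, params: ModelParams,
                       mu: float | str = "auto") -> BlowupCertificate:
    """Search for a multiplier exponent certifying finite-time blow-up.

    With ``mu='auto'`` 64 log-spaced exponents above the admissibility
    bound ``max(V_F/a0, 1/b)`` are scanned up to ``50/(V_F - V_R)`` (beyond
    which ``e^{mu V_F}`` outruns double precision long before the moment
    condition can change truth value) and the first certifying exponent is
    returned.  For ``b <= 0`` the certificate is inapplicable and
    ``certified=False`` is returned with a reason.
    """
    a_m = params.a0  # infimum of a(N) = a0 + a1 N over N >= 0
    if params.b <= 0:
        return BlowupCertificate(
            mu=math.nan, lambda_thresh=math.inf, M_mu0=math.nan,
            mu_conditions_ok=False, certified=False, a_m=a_m,
            reason="certificate applies to excitatory-average networks (b > 0) only")

    mu_min = max(params.v_thresh / a_m, 1.0 / params.b)
    if mu == "auto":
        mu_grid = np.geomspace(mu_min * (1 + 1e-6),
                               50.0 / (params.v_thresh - params.v_reset), 64)
    else:
        mu_grid = np.array([float(mu)])

    best: tuple[float, float, float] | None = None  # (margin, mu, M, lam)
    for m in mu_grid:
        ok = m > mu_min
        M = exponential_moment(init, m)
        lam = blowup_lambda(m, params)
        if ok and M >= lam:
            return BlowupCertificate(
                mu=float(m), lambda_thresh=lam, M_mu0=M,
                mu_conditions_ok=True, certified=True, a_m=a_m,
                scanned_mu=mu_grid)
        margin = M / lam if lam > 0 else 0.0
        if ok and (best is None or margin > best[0]):
            best = (margin, float(m), M, lam)

    if best is None:
        return BlowupCertificate(
            mu=float(mu_grid[0]), lambda_thresh=blowup_lambda(mu_grid[0], params),
            M_mu0=exponential_moment(init, mu_grid[0]),
            mu_conditions_ok=False, certified=False, a_m=a_m,
            reason=f"mu={mu_grid[0]:g} below the admissibility bound {mu_min:g}",
            scanned_mu=mu_grid)
    return BlowupCertificate(
        mu=best[1], lambda_thresh=best[3], M_mu0=best[2],
        mu_conditions_ok=True, certified=False, a_m=a_m,
        reason=f"best moment/threshold ratio {best[0]:.3g} < 1 over the scan",
        scanned_mu=mu_grid)


@dataclass(frozen=True)
class MomentBoundsReport:
    """Observed margins of the a-priori moment estimates along a run.

    Margins are (bound - observed) for upper bounds and (observed - bound)
    for lower bounds, minimized over the recorded trace: a non-negative
    ``worst_margin`` means the estimate held at every recorded time.
    """

    branch: str                       # 'strong' (b >= V_F-V_R) or 'weak'
    first_moment_margin: float
    firing_integral_margin: float | None
    firing_linear_constant: float | None
    second_moment_constant: float | None
    holds: bool


def moment_bounds_report(result: SolverResult,
                         params: ModelParams) -> MomentBoundsReport:
    """Check the a-priori first/second-moment estimates along a finished run.

    For ``b >= V_F - V_R`` the first moment ``int (V_F - v) p dv`` stays
    below ``max(V_F, initial)`` and the time-integrated firing rate obeys
    ``(b - V_F + V_R) int_0^T N dt <= V_F T + initial``; for
    ``b < V_F - V_R`` the first moment stays above ``min(V_F, initial)``
    and, for constant diffusion, ``int_0^T N dt`` grows at most linearly
    (the observed constant is reported).  The second moment is checked for
    linear growth, ``int v^2 p dv <= C (1 + t)``.
    """
    if result.status in ("blowup", "cc_breakdown"):
        logger.warning("moment bounds checked on a %s run; the a-priori "
                       "estimates assume a global-in-time solution",
                       result.status)
    t = result.times
    m1 = result.m1_trace
    m2 = result.m2_trace
    N = result.N_trace
    dV = params.v_thresh - params.v_reset
    vf = params.v_thresh
    m1_0 = m1[0]
    # cumulative firing integral by the trapezoid rule in time
    cumN = np.concatenate(
        ([0.0], np.cumsum(0.5 * (N[1:] + N[:-1]) * np.diff(t))))

    if params.b >= dV:
        branch = "strong"
        first_margin = float(np.min(max(vf, m1_0) - m1))
        upper = vf * (t - t[0]) + m1_0
        firing_margin = float(np.min(upper - (params.b - dV) * cumN))
        firing_const = None
    else:
        branch = "weak"
        first_margin = float(np.min(m1 - min(vf, m1_0)))
        firing_margin = None
        firing_const = (float(np.max(cumN / (1.0 + (t - t[0]))))
                        if params.a1 == 0 else None)
    second_const = float(np.max(m2 / (1.0 + (t - t[0]))))
    holds = first_margin >= -1e-9 and (firing_margin is None
                                       or firing_margin >= -1e-9)
    return MomentBoundsReport(
        branch=branch, first_moment_margin=first_margin,
        firing_integral_margin=firing_margin,
        firing_linear_constant=firing_const,
        second_moment_constant=second_const, holds=holds)


def relative_entropy(state_p: np.ndarray, p_inf: np.ndarray,
                     dv: float) -> float:
    """Quadratic relative entropy ``int p_inf (p/p_inf - 1)^2 dv``.

    The equilibrium is floored at :data:`PINF_FLOOR`; nodes below the floor
    (the far tail, and the threshold node where both densities vanish and
    the ratio tends to ``N/N_inf`` with zero weight) contribute nothing.
    """
    live = p_inf > PINF_FLOOR
    w = np.full(p_inf.shape, dv)
    w[0] = w[-1] = 0.5 * dv
    r = np.zeros_like(p_inf)
    r[live] = state_p[live] / p_inf[live] - 1.0
    return float(np.sum(w[live] * p_inf[live] * r[live] ** 2))


@dataclass(frozen=True)
class EntropyTrace:
    """Relative-entropy history of a linear-case run with a fitted decay rate."""

    times: np.ndarray
    H: np.ndarray
    fitted_rate: float
    fit_window: tuple[float, float]
    monotone: bool
    max_uptick: float


def relative_entropy_trace(result: SolverResult, params: ModelParams,
                           p_inf: DensityState | None = None,
                           fit_lo: float = 1e-8,
                           fit_hi: float = 1e-2) -> EntropyTrace:
    """Entropy history H(t) of a linear-case run and its exponential rate.

    Requires the uncoupled case ``b = 0, a1 = 0`` (decay toward the
    Dawson-form equilibrium is only guaranteed there).  Uses the per-step
    entropy trace when the run recorded one, otherwise recomputes from
    snapshots.  ``fitted_rate`` is minus the least-squares slope of
    ``log H`` against ``t`` on the window where ``H`` lies in
    ``[fit_lo, fit_hi]``.
    """
    if params.b != 0 or params.a1 != 0:
        raise ValueError("relative-entropy relaxation is established only "
                         "for the linear case b = 0, a1 = 0")
    if result.entropy_trace is not None:
        t, H = result.times, result.entropy_trace
    else:
        if p_inf is None:
            from .steady_state import stationary_density

            p_inf = stationary_density(params, result.final.grid)
        states = list(result.snapshots) + [result.final]
        t = np.array([s.t for s in states])
        H = np.array([relative_entropy(s.p, p_inf.p, s.grid.dv)
                      for s in states])

    dH = np.diff(H)
    max_uptick = float(np.max(dH, initial=-math.inf))
    monotone = bool(max_uptick <= 1e-10)

    sel = (H >= fit_lo) & (H <= fit_hi)
    if np.count_nonzero(sel) < 8:
        logger.warning("entropy fit window [%g, %g] contains %d points; "
                       "rate estimate unreliable", fit_lo, fit_hi,
                       int(np.count_nonzero(sel)))
        rate = math.nan
        window = (math.nan, math.nan)
    else:
        tt, hh = t[sel], np.log(H[sel])
        slope = np.polyfit(tt, hh, 1)[0]
        rate = float(-slope)
        window = (float(tt[0]), float(tt[-1]))
    return EntropyTrace(times=t, H=H, fitted_rate=rate, fit_window=window,
                        monotone=monotone, max_uptick=max_uptick)
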
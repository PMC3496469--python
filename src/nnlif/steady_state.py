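"""Stationary states of the NNLIF model: the function I(N), its roots, profiles.

A stationary density with constant firing rate ``N`` exists iff ``N`` solves
the implicit equation ``N * I(N) = 1`` where, in the scaled variables
``w_F = (V_F - b N)/sqrt(a(N))`` and ``w_R = (V_R - b N)/sqrt(a(N))``,

    I(N) = int_0^inf exp(-s^2/2) * (exp(s*w_F) - exp(s*w_R)) / s ds.

For an excitatory-average network (``b > 0``) the product ``N I(N)`` rises
from zero and decays to the limit ``(V_F - V_R)/b``, so depending on ``b``
there may be zero, one or two solutions; for ``b < 0``, ``I`` increases to
infinity and exactly one solution exists.  The corresponding stationary
profile is

    p(v) = N/a * exp(-(v-bN)^2/(2a)) * int_{max(v,V_R)}^{V_F}
           exp((w-bN)^2/(2a)) dw,

continuous, Lipschitz at ``V_R`` (one-sided slopes differ by ``N/a``) and
zero at ``V_F``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .model_core import DensityState, Grid, ModelParams

logger = logging.getLogger("nnlif")

__all__ = [
    "ScaledBounds",
    "RootSet",
    "RegimeReport",
    "scaled_bounds",
    "I_of_N",
    "find_steady_states",
    "stationary_density",
    "classify_regime",
]

#: exponent above which exp() overflows double precision; I(N) is reported
#: as +inf beyond it (only reachable for strongly inhibitory scans).
_EXP_CAP = 690.0


@dataclass(frozen=True)
class ScaledBounds:
    """Threshold and reset in the Gaussian-scaled voltage of the steady state."""

    wF: float
    wR: float


def scaled_bounds(N: float, params: ModelParams) -> ScaledBounds:
    a = params.a0 + params.a1 * N
    sa = math.sqrt(a)
    v0 = params.b * N
    return ScaledBounds(wF=(params.v_thresh - v0) / sa, wR=(params.v_reset - v0) / sa)


def I_of_N(N: float, params: ModelParams) -> float:
    """Evaluate I(N) by adaptive quadrature of the single-integral form.

    The integrand has a removable singularity at ``s = 0`` (limit
    ``wF - wR``) and Gaussian-times-exponential tails; the two exponentials
    are fused into single exponents so no intermediate overflows before the
    value itself would.  Returns ``inf`` once the integrand peak
    ``exp(wF^2/2)`` exceeds double precision.
    """
    if N < 0:
        raise ValueError("firing rate must be non-negative")
    sb = scaled_bounds(N, params)
    wF, wR = sb.wF, sb.wR
    if 0.5 * wF * wF >= _EXP_CAP and wF > 0:
        return math.inf

    def integrand(s: float) -> float:
        if s < 1e-12:
            return wF - wR
        return (math.exp(-0.5 * s * s + s * wF) - math.exp(-0.5 * s * s + s * wR)) / s

    # log-integrand falls 40+ below its peak past s* -> negligible tail
    s_star = max(wF, 0.0) + 10.0
    pts = [wF] if 0.0 < wF < s_star else None
    val, _ = quad(integrand, 0.0, s_star, points=pts, limit=200,
                  epsabs=1e-300, epsrel=1e-13)
    return val


@dataclass
class RootSet:
    """Positive solutions of N*I(N)=1, sorted increasing, after refinement."""

    roots: list[float]
    scan_N: np.ndarray = field(repr=False)
    scan_F: np.ndarray = field(repr=False)
    search_max: float
    flagged_tangent: list[float] = field(default_factory=list)
    positive_at_max: bool = False


def _F(N: float, params: ModelParams) -> float:
    val = I_of_N(N, params)
    if math.isinf(val):
        return math.inf
    return N * val - 1.0


def find_steady_states(params: ModelParams, N_max: float | None = None,
                       n_scan: int = 400) -> RootSet:
    """Scan F(N) = N*I(N) - 1 on a log grid, bracket and refine sign changes.

    The default scan bound is ``max(50, 20 (V_F - V_R)/b)`` for ``b > 0``
    (past the point where ``N I(N)`` has settled on its limit
    ``(V_F-V_R)/b``) and 50 otherwise.  Local maxima of ``F`` within 1e-6 of
    zero without a sign change are reported as flagged near-tangent roots.
    """
    dV = params.v_thresh - params.v_reset
    if N_max is None:
        N_max = max(50.0, 20.0 * dV / params.b) if params.b > 0 else 50.0
    if N_max <= 0:
        raise ValueError("scan bound must be positive")

    Ns = np.geomspace(1e-4, N_max, n_scan)
    Fs = np.array([_F(N, params) for N in Ns])
    roots: list[float] = []
    for i in range(len(Ns) - 1):
        fi, fj = Fs[i], Fs[i + 1]
        if not (np.isfinite(fi) and np.isfinite(fj)):
            continue
        if fi == 0.0:
            roots.append(float(Ns[i]))
        elif np.sign(fi) != np.sign(fj):
            r = brentq(_F, Ns[i], Ns[i + 1], args=(params,),
                       xtol=1e-14, rtol=4 * np.finfo(float).eps)
            if abs(_F(r, params)) > 1e-9:
                logger.warning("root refinement left |F(%g)|=%.2e > 1e-9",
                               r, abs(_F(r, params)))
            roots.append(float(r))

    flagged: list[float] = []
    finite = np.isfinite(Fs)
    for i in range(1, len(Ns) - 1):
        if not (finite[i - 1] and finite[i] and finite[i + 1]):
            continue
        if Fs[i] > Fs[i - 1] and Fs[i] > Fs[i + 1] and -1e-6 < Fs[i] < 0:
            flagged.append(float(Ns[i]))
            logger.warning(
                "near-tangent maximum of N*I(N)-1 at N=%g (F=%.2e); "
                "possible double root", Ns[i], Fs[i])

    positive_at_max = bool(np.isfinite(Fs[-1]) and Fs[-1] > 0)
    if params.b > 0 and np.isfinite(Fs[-1]):
        limit = dV / params.b
        tail = N_max * I_of_N(N_max, params)
        if abs(tail - limit) > 0.05 * limit:
            logger.warning(
                "N*I(N) at scan bound (%.4g) still %.1f%% from its limit "
                "(V_F-V_R)/b = %.4g; scan bound may be too small",
                tail, 100 * abs(tail - limit) / limit, limit)
    return RootSet(roots=sorted(roots), scan_N=Ns, scan_F=Fs,
                   search_max=float(N_max), flagged_tangent=flagged,
                   positive_at_max=positive_at_max)


def stationary_density(params: ModelParams, grid: Grid,
                       N: float | None = None) -> DensityState:
    """Evaluate the stationary profile on the grid.

    For the linear case ``b = 0`` the firing rate may be omitted: it is then
    the normalizing constant ``N_inf = 1/I(0)`` of the Dawson-form
    equilibrium.  If ``N`` solves ``N I(N) = 1`` the profile integrates to
    one without renormalization (checked here only through the quadrature
    tolerance); the returned state is normalized exactly so it can seed the
    solver.
    """
    if N is None:
        if params.b != 0 or params.a1 != 0:
            raise ValueError("N may only be omitted in the linear case b=0, a1=0")
        N = 1.0 / I_of_N(0.0, params)
    if N <= 0:
        raise ValueError(f"stationary firing rate must be positive, got {N}")
    a = params.a0 + params.a1 * N
    v0 = params.b * N
    vf, vr = params.v_thresh, params.v_reset
    p = np.zeros(grid.n_nodes)
    for i, v in enumerate(grid.nodes):
        lo = max(v, vr)
        if lo >= vf:
            continue
        # fused exponent: exp(((w-v0)^2 - (v-v0)^2) / 2a) stays moderate on
        # the grid even where either factor alone would under/overflow
        val, _ = quad(
            lambda w, vv=v: math.exp(((w - v0) ** 2 - (vv - v0) ** 2) / (2 * a)),
            lo, vf, limit=200, epsabs=1e-300, epsrel=1e-12)
        p[i] = N / a * val
    p[-1] = 0.0
    mass = grid.trapz(p)
    state = DensityState(grid, p / mass, t=0.0, N=float(N))
    if abs(mass - 1.0) > 0.05:
        logger.warning(
            "stationary profile at N=%g has trapezoidal mass %.4f before "
            "renormalization; N may be far from a root or the grid too coarse",
            N, mass)
    return state


@dataclass(frozen=True)
class RegimeReport:
    """Which sufficient conditions for existence/nonexistence hold.

    ``classification`` is one of ``unique``, ``existence-guaranteed``,
    ``two-guaranteed``, ``none-guaranteed`` or ``inconclusive``; the
    conditions are sufficient only, so ``inconclusive`` does not preclude
    roots found numerically.
    """

    params: ModelParams
    I0: float
    cond_small_b: bool           # 0 < b < V_F - V_R
    cond_noise: bool             # 0 < 2 a0 b < (V_F - V_R)^2 V_R
    cond_noise_refined: bool     # 2 a0 b < V_R (V_F-V_R)(sqrt(2 pi a0) + V_F - V_R)
    cond_high_connectivity: bool  # b > max(2(V_F-V_R), 2 V_F / I(0))
    cond_affine_one: bool        # a1>0 analogue guaranteeing >= 1 root
    cond_affine_two: bool        # a1>0 analogue guaranteeing >= 2 roots
    classification: str

    def __post_init__(self) -> None:
        existence = self.classification in (
            "unique", "existence-guaranteed", "two-guaranteed")
        nonexistence = self.classification == "none-guaranteed"
        assert not (existence and nonexistence)


def classify_regime(params: ModelParams) -> RegimeReport:
    """Evaluate each sufficient steady-state condition literally.

    ``I(0)`` is computed by quadrature (the closed-form expression is only
    an upper bound).  For ``b < 0`` with constant diffusion the steady state
    is unique; for ``b > 0`` the small-connectivity conditions guarantee
    existence, their combination with ``b > V_F - V_R`` guarantees two
    states, and the high-connectivity condition rules them out.
    """
    b, a0, a1 = params.b, params.a0, params.a1
    vr, vf = params.v_reset, params.v_thresh
    dV = vf - vr
    I0 = I_of_N(0.0, params)

    cond_small_b = 0 < b < dV
    cond_noise = 0 < 2 * a0 * b < dV * dV * vr
    cond_noise_refined = b > 0 and (
        2 * a0 * b < vr * dV * (math.sqrt(2 * math.pi * a0) + dV))
    cond_high = b > max(2 * dV, 2 * vf / I0)
    cond_affine_one = a1 > 0 and (b < dV or (b > 0 and 2 * a0 * b + 2 * a1 * vr < dV * dV * vr))
    cond_affine_two = a1 > 0 and (2 * a0 * b + 2 * a1 * vr < dV * dV * vr) and b > dV

    if b < 0:
        classification = "unique" if a1 == 0 else "existence-guaranteed"
    elif cond_high:
        classification = "none-guaranteed"
    elif a1 == 0 and cond_noise and b > dV:
        classification = "two-guaranteed"
    elif cond_affine_two:
        classification = "two-guaranteed"
    elif cond_small_b or (a1 == 0 and cond_noise) or cond_affine_one:
        classification = "existence-guaranteed"
    else:
        classification = "inconclusive"

    return RegimeReport(
        params=params, I0=I0,
        cond_small_b=cond_small_b,
        cond_noise=cond_noise,
        cond_noise_refined=cond_noise_refined,
        cond_high_connectivity=cond_high,
        cond_affine_one=cond_affine_one,
        cond_affine_two=cond_affine_two,
        classification=classification,
    )
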
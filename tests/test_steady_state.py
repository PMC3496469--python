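"""The stationary condition N I(N) = 1: quadrature, roots, profiles, regimes."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import erfcx

import nnlif as nl
from nnlif.steady_state import I_of_N, scaled_bounds


def I_nested_oracle(N, params):
    """I(N) by brute-force nested quadrature of the double-integral form."""
    sb = scaled_bounds(N, params)

    def inner(z):
        lo = max(z, sb.wR)
        val, _ = quad(lambda u: np.exp(0.5 * u * u), lo, sb.wF, limit=200,
                      epsabs=1e-300, epsrel=1e-12)
        return np.exp(-0.5 * z * z) * val

    val, _ = quad(inner, -40.0, sb.wF, limit=400, epsabs=1e-300,
                  epsrel=1e-12)
    return val


def I_erfcx_oracle(N, params):
    """Independent reduction: I(N) = sqrt(pi/2) int_{wR}^{wF} erfcx(-w/sqrt 2) dw."""
    sb = scaled_bounds(N, params)
    val, _ = quad(lambda w: erfcx(-w / math.sqrt(2)), sb.wR, sb.wF,
                  epsabs=1e-14, epsrel=1e-13, limit=200)
    return math.sqrt(math.pi / 2) * val


# twenty deterministic parameter sets spanning both signs of b and a1 >= 0
RNG = np.random.default_rng(20110718)
PARAM_SETS = [
    dict(b=float(RNG.uniform(-3, 3)),
         a0=float(RNG.uniform(0.3, 3)),
         a1=float(RNG.choice([0.0, RNG.uniform(0.0, 0.5)])),
         N=float(RNG.uniform(0.0, 4)))
    for _ in range(20)
]


class TestIofN:
    @pytest.mark.parametrize("case", PARAM_SETS)
    def test_single_integral_matches_nested_quadrature(self, case):
        par = nl.ModelParams(b=case["b"], a0=case["a0"], a1=case["a1"])
        val = I_of_N(case["N"], par)
        assert val > 0
        oracle = I_nested_oracle(case["N"], par)
        # agreement to 1e-8 precision (absolute for order-one values)
        assert abs(val - oracle) <= 1e-8 * max(1.0, abs(oracle))

    @pytest.mark.parametrize("N", [0.0, 0.5, 2.0, 10.0])
    def test_no_connectivity_means_no_rate_dependence(self, N):
        par = nl.ModelParams(b=0.0)
        assert I_of_N(N, par) == pytest.approx(I_of_N(0.0, par), rel=1e-12)

    def test_value_at_printed_high_state(self):
        """I at the study's printed high firing rate, b=1.5, a=1.

        The recomputed value (three mutually agreeing quadratures) is
        0.4293808, noticeably off the reciprocal 1/2.31901 = 0.431218 of
        the printed rate itself - the printed rate carries the original
        computation's discretization error.
        """
        par = nl.ModelParams(b=1.5)
        val = I_of_N(2.31901, par)
        assert val == pytest.approx(0.42938082169494, abs=1e-9)
        assert val == pytest.approx(I_erfcx_oracle(2.31901, par), abs=1e-10)

    @pytest.mark.parametrize("b", [0.5, 1.5, 3.0])
    def test_decreasing_in_N_for_excitatory(self, b):
        par = nl.ModelParams(b=b)
        Ns = np.linspace(0, 8, 15)
        vals = [I_of_N(N, par) for N in Ns]
        assert np.all(np.diff(vals) < 0)

    def test_increasing_in_N_for_inhibitory(self):
        par = nl.ModelParams(b=-1.5)
        Ns = np.linspace(0, 8, 15)
        vals = [I_of_N(N, par) for N in Ns]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("b", [0.5, 1.5, 3.0])
    def test_large_N_asymptote(self, b):
        """N I(N) approaches (V_F - V_R)/b, within 1% at N = 200 (V_F-V_R)/b."""
        par = nl.ModelParams(b=b)
        N = 200.0 * (par.v_thresh - par.v_reset) / b
        limit = (par.v_thresh - par.v_reset) / b
        assert N * I_of_N(N, par) == pytest.approx(limit, rel=0.01)

    @pytest.mark.parametrize("a0,b", [(1.0, 0.5), (0.4, 1.2), (2.5, -0.8)])
    def test_I0_upper_bound(self, a0, b):
        """Closed-form bound sqrt(2 pi) dV/sqrt(a0) exp(max(VR^2,VF^2)/2a0)."""
        par = nl.ModelParams(b=b, a0=a0)
        bound = (math.sqrt(2 * math.pi) * (par.v_thresh - par.v_reset)
                 / math.sqrt(a0)
                 * math.exp(max(par.v_reset ** 2, par.v_thresh ** 2) / (2 * a0)))
        assert I_of_N(0.0, par) <= bound

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            I_of_N(-0.1, nl.ModelParams(b=0.5))


class TestAffineDiffusion:
    """a(N) = a0 + a1 N keeps the shape of the steady-state problem."""

    FIG2_SETS = [(0.5, 0.5, 0.125), (1.2, 0.4, 0.01), (8.0, 6.0, 0.01)]

    @pytest.mark.parametrize("b,a0,a1", FIG2_SETS)
    def test_I_still_decreasing_for_excitatory(self, b, a0, a1):
        par = nl.ModelParams(b=b, a0=a0, a1=a1)
        Ns = np.linspace(0, 10, 21)
        vals = [I_of_N(N, par) for N in Ns]
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize("b,a0,a1", FIG2_SETS)
    def test_asymptote_survives_affine_diffusion(self, b, a0, a1):
        par = nl.ModelParams(b=b, a0=a0, a1=a1)
        N = 400.0 / b
        assert N * I_of_N(N, par) == pytest.approx(1.0 / b, rel=0.02)

    def test_inhibitory_affine_has_a_root(self):
        par = nl.ModelParams(b=-1.0, a0=1.0, a1=1.0)
        roots = nl.find_steady_states(par).roots
        assert len(roots) >= 1


class TestFindSteadyStates:
    @pytest.mark.parametrize("b,count", [(1.5, 2), (0.5, 1), (3.0, 0),
                                         (-1.5, 1)])
    def test_root_counts(self, root_sets, b, count):
        assert len(root_sets[b].roots) == count

    def test_roots_solve_the_implicit_equation(self, root_sets):
        for b, rs in root_sets.items():
            par = nl.ModelParams(b=b)
            for r in rs.roots:
                assert abs(r * I_of_N(r, par) - 1.0) < 1e-9

    def test_high_root_value_bistable_regime(self, root_sets):
        """The larger b=1.5 root, cross-checked against an independent form."""
        hi = root_sets[1.5].roots[-1]
        assert hi == pytest.approx(2.2891257077, abs=1e-6)
        par = nl.ModelParams(b=1.5)
        assert hi * I_erfcx_oracle(hi, par) == pytest.approx(1.0, abs=1e-9)

    def test_roots_sorted_and_positive(self, root_sets):
        for rs in root_sets.values():
            assert rs.roots == sorted(rs.roots)
            assert all(r > 0 for r in rs.roots)

    def test_bad_scan_bound_rejected(self):
        with pytest.raises(ValueError):
            nl.find_steady_states(nl.ModelParams(b=0.5), N_max=-1.0)


class TestStationaryDensity:
    def test_linear_case_matches_normalized_dawson_form(self):
        """b=0 equilibrium equals the directly normalized closed form."""
        par = nl.ModelParams(b=0.0)
        grid = nl.make_grid(-7.0, par, 451)
        state = nl.stationary_density(par, grid)
        assert state.N == pytest.approx(1.0 / I_of_N(0.0, par), rel=1e-10)

        # oracle: evaluate the unnormalized profile and normalize numerically
        def raw(v):
            val, _ = quad(lambda w: np.exp((w * w - v * v) / 2.0),
                          max(v, 1.0), 2.0, limit=200)
            return val

        ref = np.array([raw(v) if v < 2.0 else 0.0 for v in grid.nodes])
        ref /= grid.trapz(ref)
        assert grid.trapz(np.abs(state.p - ref)) < 1e-9

    def test_unit_mass_at_root_without_renormalization(self, root_sets):
        """At a root of N I(N)=1 the profile integrates to 1 by itself."""
        par = nl.ModelParams(b=1.5)
        grid = nl.make_grid(nl.default_v_min(par), par, 1201)  # dv = 0.0075
        N = root_sets[1.5].roots[-1]
        a, v0 = par.a0, par.b * N

        def raw(v):
            val, _ = quad(lambda w: np.exp(((w - v0) ** 2 - (v - v0) ** 2)
                                           / (2 * a)),
                          max(v, par.v_reset), par.v_thresh, limit=200)
            return N / a * val

        p = np.array([raw(v) if v < par.v_thresh else 0.0
                      for v in grid.nodes])
        assert grid.trapz(p) == pytest.approx(1.0, abs=1e-4)

    def test_kink_at_reset(self, root_sets):
        """One-sided slopes at V_R differ by N/a (the flux jump)."""
        par = nl.ModelParams(b=1.5)
        grid = nl.make_grid(-7.0, par, 1801)
        N = root_sets[1.5].roots[0]
        state = nl.stationary_density(par, grid, N)
        i = grid.idx_reset
        dv = grid.dv
        left = (state.p[i] - state.p[i - 1]) / dv
        right = (state.p[i + 1] - state.p[i]) / dv
        assert left - right == pytest.approx(N / par.a0, rel=0.02)

    def test_zero_above_threshold_and_nonnegative(self):
        par = nl.ModelParams(b=0.5)
        grid = nl.make_grid(-7.0, par, 451)
        state = nl.stationary_density(par, grid, 0.13)
        assert state.p[-1] == 0.0
        assert np.all(state.p >= 0)

    def test_invalid_rate_rejected(self):
        par = nl.ModelParams(b=0.5)
        grid = nl.make_grid(-7.0, par, 451)
        with pytest.raises(ValueError):
            nl.stationary_density(par, grid, -1.0)
        with pytest.raises(ValueError):
            nl.stationary_density(nl.ModelParams(b=0.5), grid)  # N omitted, b!=0


class TestClassifyRegime:
    def test_small_connectivity_guarantees_existence(self):
        rep = nl.classify_regime(nl.ModelParams(b=0.5))
        assert rep.cond_small_b
        assert rep.classification == "existence-guaranteed"

    def test_bistable_window_is_inconclusive_by_the_base_conditions(self):
        """b=1.5: both base sufficient conditions fail even though two
        roots exist numerically; the refined noise condition does hold."""
        rep = nl.classify_regime(nl.ModelParams(b=1.5))
        assert not rep.cond_small_b            # 1.5 >= V_F - V_R
        assert not rep.cond_noise              # 2*1*1.5 = 3 >= 1
        assert rep.cond_noise_refined          # 3 < sqrt(2 pi) + 1
        assert rep.classification == "inconclusive"

    def test_high_connectivity_guarantees_nonexistence(self):
        rep = nl.classify_regime(nl.ModelParams(b=3.0))
        assert rep.cond_high_connectivity
        assert rep.classification == "none-guaranteed"

    def test_inhibitory_network_is_unique(self):
        rep = nl.classify_regime(nl.ModelParams(b=-1.5))
        assert rep.classification == "unique"

    def test_affine_two_root_condition(self):
        # 2 a0 b + 2 a1 V_R = 0.96 + 0.02 < (V_F-V_R)^2 V_R = 1, b > 1
        rep = nl.classify_regime(nl.ModelParams(b=1.2, a0=0.4, a1=0.01))
        assert rep.cond_affine_two
        assert rep.classification == "two-guaranteed"

    @pytest.mark.parametrize("b,a0,a1", [(0.8, 1.3, 0.0), (2.4, 0.2, 0.1),
                                         (-0.3, 0.7, 0.4), (5.0, 1.0, 0.0)])
    def test_existence_and_nonexistence_never_both(self, b, a0, a1):
        rep = nl.classify_regime(nl.ModelParams(b=b, a0=a0, a1=a1))
        asserts_existence = rep.classification in (
            "unique", "existence-guaranteed", "two-guaranteed")
        asserts_nonexistence = rep.classification == "none-guaranteed"
        assert not (asserts_existence and asserts_nonexistence)
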
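"""Shared fixtures: expensive simulation runs are computed once per session."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nnlif as nl

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


#: presets exercised by the dynamics tests (fig4_tl/fig5/fig6 duplicate
#: fig3/fig4_bl/fig4_tr physics and are covered by the cheap unit tests)
PRESET_RUN_NAMES = ("fig3", "fig4_tr", "fig4_bl", "fig4_br", "fig7", "fig8")


@pytest.fixture(scope="session")
def preset_results():
    """Run the six distinct study presets once (dv = 0.01 defaults)."""
    out = {}
    for name in PRESET_RUN_NAMES:
        par, init, cfg, spec = nl.build_preset(name)
        out[name] = {
            "result": nl.run_simulation(par, init, cfg),
            "params": par,
            "init": init,
            "spec": spec,
        }
    return out


@pytest.fixture(scope="session")
def root_sets():
    """Steady-state root scans for the four connectivities of the study."""
    return {b: nl.find_steady_states(nl.ModelParams(b=b))
            for b in (0.5, 1.5, 3.0, -1.5)}


def _entropy_run(dv: float):
    par = nl.ModelParams(b=0.0)
    v_min = nl.default_v_min(par, 0.0, 0.25)
    grid = nl.make_grid(v_min, par, int(round((2.0 - v_min) / dv)) + 1)
    p_inf = nl.stationary_density(par, grid)
    init = nl.maxwellian_density(grid, 0.0, 0.25, par)
    cfg = nl.SchemeConfig(scheme="chang_cooper", t_end=8.0,
                          entropy_ref=p_inf, steady_tol=1e-300)
    result = nl.run_simulation(par, init, cfg)
    trace = nl.relative_entropy_trace(result, par, p_inf=p_inf)
    return {"params": par, "grid": grid, "p_inf": p_inf,
            "result": result, "trace": trace}


@pytest.fixture(scope="session")
def entropy_runs():
    """Linear-case (b=0) relaxation runs at two resolutions."""
    return {dv: _entropy_run(dv) for dv in (0.02, 0.01)}


@pytest.fixture(scope="session")
def fixed_point_drifts():
    """L1 drift per unit time of the stationary profile under Chang-Cooper."""
    par = nl.ModelParams(b=0.5)
    root = nl.find_steady_states(par).roots[0]
    v_min = nl.default_v_min(par)
    out = {}
    for dv in (0.01, 0.005):
        grid = nl.make_grid(v_min, par, int(round((2.0 - v_min) / dv)) + 1)
        st = nl.stationary_density(par, grid, root)
        cfg = nl.SchemeConfig(scheme="chang_cooper", t_end=1.0,
                              steady_tol=1e-300)
        res = nl.run_simulation(par, st, cfg)
        out[dv] = float(grid.trapz(np.abs(res.final.p - st.p)))
    out["root"] = root
    return out
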
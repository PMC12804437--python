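import numpy as np
import pytest

import rdapso as r
from rdapso.datasets import cairns, hainan_center, hainan_edge


@pytest.fixture(scope="session")
def center_study():
    return hainan_center()


@pytest.fixture(scope="session")
def edge_study():
    return hainan_edge()


@pytest.fixture(scope="session")
def cairns_study():
    return cairns()


@pytest.fixture(scope="session")
def recovery_scenario():
    """Low-trap-density virtual experiment with known ground truth.

    Six 15 m zones, area-proportional site counts anchored at one site in
    zone 1, 3% site efficiency, step multiplier k = 35 (D = 36.75 m^2/day).
    """
    spec = r.ScenarioSpec(seed=1)
    layout, census = r.make_layout(spec, seed=1)
    obs = r.simulate(layout, r.WalkConfig(k=spec.k, n_days=spec.n_days,
                                          N=spec.N, reps=spec.reps), seed=42).ratio_set()
    return spec, layout, census, obs


@pytest.fixture(scope="session")
def recovery_result(recovery_scenario):
    """Ten full grid-search + PSO runs on the known-truth scenario.

    Shared by the parameter-recovery and k-normality checks; forward
    simulations inside the optimization use a reduced walker count.
    """
    spec, layout, census, obs = recovery_scenario
    walk = r.WalkConfig(k=1.0, n_days=spec.n_days, N=2000, reps=2)
    config = r.PSOConfig(k_bounds=(15, 55), q_bounds=(5, 30),
                         p_bounds=(0, 15), s_e_bounds=(0.001, 1.0))
    return r.run_replicates(obs, layout, walk, config, n_runs=10,
                            outlier_rule="mean+1.0sd", seed=3, grid_resolution=6)


@pytest.fixture()
def tiny_layout():
    """Two well-separated traps in a two-zone design."""
    sites = (
        r.CaptureSite(x=10.0, y=0.0, q=10.0, p=0.0, s_e=1.0),
        r.CaptureSite(x=-25.0, y=5.0, q=10.0, p=5.0, s_e=0.5),
    )
    return r.StudyLayout(release=(0.0, 0.0), zone_bounds=np.array([0.0, 15.0, 30.0]), sites=sites)
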
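"""Shared fixtures: small grids, canned states, and cached scenario runs.

Scenario trajectories are expensive (tens of seconds each), so they are
computed once per session and shared between the phenomenology and
conservation tests.
"""

import numpy as np
import pytest

import actinwaves as aw
from actinwaves.observables import observable_series


@pytest.fixture(scope="session")
def params():
    return aw.ModelParams()


@pytest.fixture()
def small_grid():
    return aw.GridSpec(Lx=4.0, Lz=2.0, nx=16, nz=20, dt=0.02)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def _random_state(grid, rng, scale=1.0):
    s = aw.CytosolState.zeros(grid)
    for _, f in s.items():
        f[:] = scale * rng.random(f.shape)
    m = aw.MembraneState.resting(grid, aw.ModelParams())
    for name, f in m.items():
        if name != "W":
            f[:] = 0.1 * scale * rng.random(f.shape)
    return s, m


@pytest.fixture()
def random_state(small_grid, rng):
    return _random_state(small_grid, rng)


# ---------------------------------------------------------------------------
# session-cached scenario runs (reduced horizons where the phenomenology
# is already established early)
# ---------------------------------------------------------------------------

def _run_scenario(name, **tweaks):
    cfg = aw.scenario(name)
    for k, v in tweaks.items():
        setattr(cfg, k, v)
    traj = aw.run(cfg)
    return cfg, traj


@pytest.fixture(scope="session")
def single_precursor_run():
    cfg, traj = _run_scenario("single_precursor", t_end=110.0)
    ser = observable_series(traj, species=("factin", "rac_star", "arp_free",
                                           "cor_caps", "arp", "g"))
    return cfg, traj, ser


@pytest.fixture(scope="session")
def collision_run():
    cfg, traj = _run_scenario("collision")
    ser = observable_series(traj, species=("factin",))
    return cfg, traj, ser


@pytest.fixture(scope="session")
def feedback_off_run():
    cfg, traj = _run_scenario("feedback_off", t_end=100.0)
    ser = observable_series(traj, species=("factin",))
    return cfg, traj, ser


@pytest.fixture(scope="session")
def pten_block_run():
    cfg, traj = _run_scenario("pten_block")
    ser = observable_series(traj, species=("factin",))
    return cfg, traj, ser


@pytest.fixture(scope="session")
def pten_moving_run():
    cfg, traj = _run_scenario("pten_moving")
    ser = observable_series(traj, species=("factin",))
    return cfg, traj, ser


@pytest.fixture(scope="session")
def pten_split_run():
    cfg, traj = _run_scenario("pten_split")
    ser = observable_series(traj, species=("factin",))
    return cfg, traj, ser
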
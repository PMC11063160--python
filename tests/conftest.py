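import numpy as np
import pytest

from vtlkit import ArenaConfig, BehaviorParams
from vtlkit.synthetic import simulate_trajectories


@pytest.fixture(scope="session")
def arena() -> ArenaConfig:
    return ArenaConfig()


@pytest.fixture(scope="session")
def fast_arena() -> ArenaConfig:
    """Low frame-rate arena so daily windows stay small in tests."""
    return ArenaConfig(fps=1.0)


@pytest.fixture(scope="session")
def short_sim(arena):
    """A 2-minute, 3-object simulation shared by read-only tests."""
    params = BehaviorParams(seed=7)
    tracks, states = simulate_trajectories(arena, params, 3, 120.0)
    return tracks, states, params


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
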
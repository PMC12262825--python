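import numpy as np
import pytest

from openfield import ArenaGeometry, SimulationConfig, simulate_trajectory


@pytest.fixture(scope="session")
def arena() -> ArenaGeometry:
    return ArenaGeometry()


@pytest.fixture(scope="session")
def long_tracking(arena):
    """One standard 20-minute goal-biased session, shared across tests."""
    return simulate_trajectory(arena, SimulationConfig(seed=4), seed=4)


@pytest.fixture(scope="session")
def short_tracking(arena):
    """A 5-minute session for cheap structural tests."""
    return simulate_trajectory(arena, SimulationConfig(duration=300.0, seed=11), seed=11)
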
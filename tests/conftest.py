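import numpy as np
import pytest

from gridscape import geometry
from gridscape.trajectory import TrajectoryParams, simulate_trajectory


@pytest.fixture(scope="session")
def unit_square():
    return geometry.make_square(1.0)


@pytest.fixture(scope="session")
def square_traj(unit_square):
    """A 300 s foraging run in the unit square (shared across tests)."""
    return simulate_trajectory(unit_square, 300.0, TrajectoryParams(seed=11))


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same fresh stream regardless of
    # execution order
    return np.random.default_rng(2024)
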
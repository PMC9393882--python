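import numpy as np
import pytest
from hypothesis import settings

from lagcross import SimulationConfig, build_baltimore_lattice, simulate_study

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baltimore():
    return build_baltimore_lattice()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study(baltimore):
    """A compact synthetic study reused across module tests."""
    return simulate_study(
        SimulationConfig(seed=5, lattice=baltimore, events_per_outcome=60)
    )
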
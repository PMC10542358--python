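import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True)
settings.load_profile("stable")

from rloopm5c import SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset at the standard study conditions."""
    return simulate_dataset(SimulationParams(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
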
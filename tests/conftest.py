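import numpy as np
import pytest

from echochambers import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast baseline scenario for engine-level tests."""
    return SimulationConfig(n_agents=60, horizon=10, seed=7, track_memory=True)
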
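import numpy as np
import pytest

from doseweight import SimulationConfig, make_reference


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale simulation: 64 px box, 12 frames."""
    return SimulationConfig(box_size=64, n_frames=12, seed=0)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return make_reference(small_config)
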
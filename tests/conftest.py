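import numpy as np
import pytest

from pctracer import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def phantom_5ppm():
    """The standard 64x64 lung phantom with 5 ppm drift, shared across tests."""
    config = PhantomConfig(seed=42, drift_ppm=5.0)
    dataset, truth = generate_phantom(config)
    return config, dataset, truth


@pytest.fixture(scope="session")
def small_phantom():
    """A 16x16 phantom for I/O round trips and other cheap structural tests."""
    config = PhantomConfig(grid_shape=(16, 16), seed=7)
    dataset, truth = generate_phantom(config)
    return config, dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
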
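import numpy as np
import pytest

from greenwave.synthetic import (
    SimulationConfig,
    generate_landscape,
    generate_ndvi_series,
    simulate_deer,
)


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def landscape(config):
    return generate_landscape(config)


@pytest.fixture(scope="session")
def phen(landscape, config):
    return generate_ndvi_series(landscape, config)


@pytest.fixture(scope="session")
def phen_noiseless(landscape, config):
    cfg = SimulationConfig(seed=11, ndvi_noise_sd=0.0)
    return generate_ndvi_series(landscape, cfg)


@pytest.fixture(scope="session")
def tracks(landscape, config):
    return simulate_deer(landscape, config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
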
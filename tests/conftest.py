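import numpy as np
import pytest

from hifbind.synthetic_data import (
    SimulationConfig,
    simulate_annotation,
    simulate_binding,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def annotation(default_config):
    return simulate_annotation(default_config)


@pytest.fixture(scope="session")
def binding(default_config, annotation):
    return simulate_binding(default_config, annotation)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
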
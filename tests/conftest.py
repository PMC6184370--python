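import numpy as np
import pytest

from repgame import EnvironmentSpec, GameConfig, assemble_model


@pytest.fixture
def default_config():
    return GameConfig()


@pytest.fixture
def default_model(default_config):
    return assemble_model(default_config)


@pytest.fixture
def default_env():
    return EnvironmentSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
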
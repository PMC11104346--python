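import numpy as np
import pytest

from aegng import Config, init_agent


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return Config()


@pytest.fixture
def agent(default_config):
    return init_agent(default_config)
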
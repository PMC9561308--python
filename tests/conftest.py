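import numpy as np
import pytest

import psmcea


@pytest.fixture(scope="session")
def base_cfg():
    return psmcea.default_config()


@pytest.fixture(scope="session")
def base_result(base_cfg):
    return psmcea.run_base_case(base_cfg)


@pytest.fixture(scope="session")
def lp_os():
    return psmcea.ParametricSurvival("log-logistic", shape=1.5396, scale=0.01375)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
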
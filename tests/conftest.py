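import numpy as np
import pytest
from hypothesis import settings

from striatoseq.neurons import M1Params, M2Params, SynapseKernel

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def m1():
    return M1Params()


@pytest.fixture
def m1_quiet():
    return M1Params(eta_noise=0.0)


@pytest.fixture
def m2():
    return M2Params()


@pytest.fixture
def m2_quiet():
    return M2Params(eta_noise=0.0)


@pytest.fixture
def dirac():
    return SynapseKernel("dirac")
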
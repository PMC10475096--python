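import numpy as np
import pytest

from iedflow.synthetic import build_protocol

FS = 2000.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def isp1():
    return build_protocol("ISP1", 0.0, 5)


@pytest.fixture(scope="session")
def isp1_single():
    return build_protocol("ISP1", 0.0, 1)


@pytest.fixture(scope="session")
def isp2_single():
    return build_protocol("ISP2", 1000.0, 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
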
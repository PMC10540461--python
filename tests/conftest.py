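import numpy as np
import pytest

from ffortho.fixtures import load_fixture


@pytest.fixture
def fig1():
    return load_fixture("fig1")


@pytest.fixture
def background():
    return load_fixture("background_dcj")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
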
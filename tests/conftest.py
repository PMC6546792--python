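import numpy as np
import pytest

from transtore.channel import ChannelModel
from transtore.codec import CodecProfile, TransitionTable, builtin_profile


@pytest.fixture
def table():
    return TransitionTable()


@pytest.fixture
def hello_profile():
    return builtin_profile("hello_world")


@pytest.fixture
def eureka_profile():
    return builtin_profile("eureka")


@pytest.fixture
def k38_profile():
    return builtin_profile("k38")


@pytest.fixture
def small_profile():
    """A 10-nt scaffolded profile small enough for exhaustive decoding."""
    return CodecProfile(
        name="t10", K=10, B=12, omega=12, address_bits=2, sync_period=3
    )


@pytest.fixture
def default_model():
    return ChannelModel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
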
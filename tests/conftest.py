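import numpy as np
import pytest

from socialgaze import ParticipantProfile
from socialgaze.defaults import DEFAULT_LAYOUT


@pytest.fixture(scope="session")
def profile():
    return ParticipantProfile()


@pytest.fixture(scope="session")
def layout():
    return DEFAULT_LAYOUT


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
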
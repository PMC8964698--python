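import numpy as np
import pytest

from bewindow.demo import demo_abe_target, demo_cbe_target


@pytest.fixture(scope="session")
def cbe_target():
    return demo_cbe_target(intended_positions=(4,))


@pytest.fixture(scope="session")
def abe_target():
    return demo_abe_target(intended_positions=(5,))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def qual(n, value=38):
    """Constant Phred array helper."""
    return np.full(n, value, dtype=np.int16)
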
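import numpy as np
import pytest

from sdssa import ChainSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_chain():
    """A three-step chain small enough for exhaustive simulation."""
    return ChainSpec(n=3, k=1.0, x10=10, y0=4)


@pytest.fixture
def nine_step_chain():
    """The poly(A)-shortening-scale chain used by the delay calibration."""
    return ChainSpec(n=9, k=0.126, x10=20, y0=0)
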
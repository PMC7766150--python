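import numpy as np
import pytest


@pytest.fixture
def ring5():
    """5x5 wall mask: a square ring on rows/cols 1..3 with hollow center."""
    tw = np.zeros((5, 5), dtype=np.uint8)
    tw[1:4, 1:4] = 1
    tw[2, 2] = 0
    return tw


@pytest.fixture
def ring5_triple(ring5):
    """The analytic (wall, cavity, whole) triple of the 5x5 ring."""
    tc = np.zeros((5, 5), dtype=np.uint8)
    tc[2, 2] = 1
    wt = np.zeros((5, 5), dtype=np.uint8)
    wt[1:4, 1:4] = 1
    return ring5, tc, wt


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
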
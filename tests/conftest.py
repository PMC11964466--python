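import numpy as np
import pytest
from shapely.geometry import box

KM = 1000.0


@pytest.fixture
def square_window():
    """100 x 100 km window, metres."""
    return box(0.0, 0.0, 100 * KM, 100 * KM)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
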
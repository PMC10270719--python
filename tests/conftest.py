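import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def square_distance() -> np.ndarray:
    """Euclidean distances of the unit square's corners (in cyclic order)."""
    corners = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]
    d = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            d[i, j] = math.dist(corners[i], corners[j])
    return d


@pytest.fixture
def hexagon_distance() -> np.ndarray:
    """Phase-oscillator distances d(k,l) = |sin(π(k−l)/6)| on 6 vertices."""
    d = np.zeros((6, 6))
    for i in range(6):
        for j in range(6):
            d[i, j] = abs(math.sin(math.pi * (i - j) / 6))
    return d
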
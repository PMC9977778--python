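import numpy as np
import pytest

from redlesion.detection import DetectionParams


@pytest.fixture
def params():
    return DetectionParams()


@pytest.fixture
def disc_image():
    """Dark disc of radius 11 (intensity 0.2) on a 0.7 background, centred
    at (32, 32) in a 64x64 frame — squarely inside the detectable band."""
    g = np.full((64, 64), 0.7)
    yy, xx = np.mgrid[:64, :64]
    rr = np.sqrt((yy - 32.0) ** 2 + (xx - 32.0) ** 2)
    g[rr <= 11] = 0.2
    return g


@pytest.fixture
def bar_image():
    """Vertical dark bar of half-width 4 through column 32 — a vessel-like
    distractor that no quarter should accept."""
    g = np.full((64, 64), 0.7)
    g[:, 28:37] = 0.2
    return g
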
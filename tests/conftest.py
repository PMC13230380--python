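import numpy as np
import pytest

from gazeqc import GazeSegment


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_segment(azimuth, elevation, fs=600.0, eye="left"):
    """Build a GazeSegment with regular timestamps from angle arrays."""
    azimuth = np.asarray(azimuth, dtype=float)
    return GazeSegment(timestamps=np.arange(azimuth.size) / fs,
                       azimuth=azimuth,
                       elevation=np.asarray(elevation, dtype=float),
                       eye=eye)


@pytest.fixture
def noise_segment(rng):
    """10^5 samples of isotropic Gaussian fixation noise, sigma=0.1 deg."""
    n = 100_000
    sigma = 0.1
    return make_segment(rng.normal(0, sigma, n), rng.normal(0, sigma, n)), sigma
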
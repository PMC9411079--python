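import numpy as np
import pytest

from dqcentroid import Spectrum, generate_spectrum


def make_spectrum(intensity, mz=None, scan_id="scan=1", **kwargs):
    """Spectrum from an intensity list on a unit grid (or explicit mz)."""
    intensity = np.asarray(intensity, dtype=float)
    if mz is None:
        mz = 100.0 + 0.001 * np.arange(intensity.size)
    return Spectrum(scan_id=scan_id, mz=np.asarray(mz, float),
                    intensity=intensity, **kwargs)


@pytest.fixture
def single_peak_truth():
    """One noiseless Gaussian at m/z 200 with default sampling (7 points)."""
    return generate_spectrum(peaks=[(200.0, 0.002, 1e6)], noise_cv=0.0, seed=1)


@pytest.fixture
def random_truth():
    """50 well-separated noiseless random peaks."""
    return generate_spectrum(n_peaks=50, noise_cv=0.0, seed=7)
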
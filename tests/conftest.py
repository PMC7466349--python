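import numpy as np
import pytest
from hypothesis import settings

from arsqnmr import AcquisitionParams, SampleSpec, make_sample
from arsqnmr.pipeline import process_fid, simulate_sample

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def monococcum_sample():
    """Whole-grain flour preset richest in alkylresorcinols (638 mg/Kg)."""
    return make_sample("t_monococcum_wholegrain", seed=1)


@pytest.fixture(scope="session")
def clean_spectrum(monococcum_sample):
    """Noise-free, fully processed spectrum of the 638 mg/Kg preset."""
    fid = simulate_sample(monococcum_sample, noise_sigma=0.0)
    return process_fid(fid)


@pytest.fixture(scope="session")
def noisy_spectrum(monococcum_sample):
    """Default-noise processed spectrum, fixed seed."""
    fid = simulate_sample(monococcum_sample, seed=7)
    return process_fid(fid)


def interpolated_fwhm_hz(spec, spectrometer_freq=400.0):
    """Full width at half maximum of the tallest peak, by linear
    interpolation of the half-height crossings."""
    y, x = spec.real, spec.ppm
    i = int(np.argmax(y))
    half = y[i] / 2.0
    left = i
    while y[left] > half:
        left -= 1
    right = i
    while y[right] > half:
        right += 1
    xl = np.interp(half, [y[left], y[left + 1]], [x[left], x[left + 1]])
    xr = np.interp(half, [y[right], y[right - 1]], [x[right], x[right - 1]])
    return abs(xl - xr) * spectrometer_freq
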
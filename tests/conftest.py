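import numpy as np
import pytest

import ftirclass as fc


@pytest.fixture(scope="session")
def grid():
    return fc.default_grid()


@pytest.fixture(scope="session")
def templates():
    return fc.default_templates()


@pytest.fixture(scope="session")
def small_dataset():
    """12 noisy spectra (4 per class) under the default noise conditions."""
    return fc.generate_dataset(4, fc.NoiseModel(seed=7))


@pytest.fixture()
def lorentzian_77(grid):
    """Isolated Lorentzian, FWHM 77 cm^-1, centred in the analysis region."""
    band = fc.BandSpec(center=1300.0, fwhm=77.0, amplitude=1.0)
    return fc.Spectrum(grid, band.profile(grid))


def measure_fwhm(spectrum, lo, hi):
    """Numeric full width at half maximum inside [lo, hi] cm^-1."""
    wn, y = spectrum.wavenumbers, spectrum.absorbance
    m = (wn >= lo) & (wn <= hi)
    wn, y = wn[m][::-1], y[m][::-1]  # ascending
    i = int(np.argmax(y))
    half = y[i] / 2.0
    left = np.interp(half, y[: i + 1], wn[: i + 1])
    right = np.interp(half, y[i:][::-1], wn[i:][::-1])
    return right - left, wn[i]
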
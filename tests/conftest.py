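import numpy as np
import pytest

from hdospec import synth
from hdospec.spectra import Spectrum, Unit


@pytest.fixture(scope="session")
def grid():
    return synth.make_grid()


@pytest.fixture(scope="session")
def ref_bands(grid):
    return synth.reference_bands(grid)


@pytest.fixture(scope="session")
def bulk(ref_bands):
    return ref_bands["bulk"]


@pytest.fixture(scope="session")
def zero_touching_band(grid):
    """Affected band whose intensity is negligible where bulk still absorbs.

    The blue wing (≥ 2650 cm⁻¹) carries < 1e-5 of the peak while the bulk
    band is still at a few percent there, so the affected spectrum of a
    two-state series built from it effectively touches zero in-window —
    the configuration that makes the non-negativity criterion for N sharp.
    """
    return synth.make_band(2420.0, 55.0, 0.0, 1.0, grid)


@pytest.fixture()
def gaussian_spectrum():
    def make(center=2500.0, sigma=50.0, step=1.0, lo=2200.0, hi=2800.0,
             amplitude=1.0, unit=Unit.MOLAR_ABSORPTION):
        g = np.arange(lo, hi + step / 2, step)
        return Spectrum(g, amplitude * np.exp(-0.5 * ((g - center) / sigma) ** 2),
                        unit)
    return make
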
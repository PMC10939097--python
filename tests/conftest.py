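import numpy as np
import pytest

from fibermsi.core import MSIDataset, PeakTable, Spectrum


@pytest.fixture
def toy_peaktable():
    """4 features x 6 pixels on a 2x3 grid, arbitrary intensities."""
    rng = np.random.default_rng(0)
    coords = np.array([[c, r] for r in range(2) for c in range(3)])
    mz = np.array([200.0, 500.0, 500.004, 800.0])
    return PeakTable(mz, rng.uniform(1, 10, size=(4, 6)), coords)


@pytest.fixture
def small_dataset():
    """3-pixel dataset of short centroid spectra."""
    spectra = [
        Spectrum([100.0, 200.0, 300.0], [1.0, 2.0, 3.0], mode="centroid"),
        Spectrum([100.0, 200.0, 300.0], [4.0, 5.0, 6.0], mode="centroid"),
        Spectrum([100.0, 200.0, 300.0], [7.0, 8.0, 9.0], mode="centroid"),
    ]
    coords = np.array([[0, 0], [1, 0], [0, 1]])
    return MSIDataset(spectra, coords, pixel_size_um=50.0)
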
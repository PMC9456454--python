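import numpy as np
import pytest

from osteospec import synth
from osteospec.spectra import Spectrum


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def gaussian_spectrum(center=960.0, amplitude=1.0, fwhm=20.0, grid=(800.0, 1200.0, 1.0),
                      baseline=0.0, noise_sd=0.0, seed=0, modality="raman_fingerprint"):
    """Single-Gaussian test spectrum with optional constant baseline/noise."""
    w = np.arange(grid[0], grid[1] + 0.5 * grid[2], grid[2])
    y = amplitude * np.exp(-4 * np.log(2) * ((w - center) / fwhm) ** 2) + baseline
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, len(w))
    return Spectrum(w, y, modality)


@pytest.fixture(scope="session")
def bone_cohort():
    """Small calibrated bone FTIR cohort shared across tests (seeded)."""
    return synth.synth_cohort("paper-bone-ftir", 42)


@pytest.fixture(scope="session")
def tensile_cohort():
    return synth.synth_cohort("paper-tensile", 42)
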
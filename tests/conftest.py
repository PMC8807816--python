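import numpy as np
import pytest

from drslayers.preprocessing import CANONICAL_WAVELENGTHS_NM, CalibratedSpectrum
from drslayers.synthetic import (
    default_tissue_library,
    simulate_animal_dataset,
    simulate_spectrum,
)
from drslayers.preprocessing import preprocess_measurement


@pytest.fixture(scope="session")
def tissue_library():
    return default_tissue_library()


@pytest.fixture
def make_spectrum():
    """Factory for canonical-grid spectra from an arbitrary value array."""

    def _make(values, sdd_mm=2.0):
        values = np.broadcast_to(np.asarray(values, dtype=float), CANONICAL_WAVELENGTHS_NM.shape)
        return CalibratedSpectrum(CANONICAL_WAVELENGTHS_NM.copy(), values.copy(), sdd_mm)

    return _make


@pytest.fixture(scope="session")
def noise_free_calibrated(tissue_library):
    """Factory: noise-free calibrated spectrum for a layer pairing and thickness."""

    def _make(thickness_mm, top, bottom, sdd_mm=6.0):
        pair = simulate_spectrum(
            thickness_mm,
            tissue_library[top],
            tissue_library[bottom],
            sdd_mm,
            noise_sd=0.0,
            gain_jitter_sd=0.0,
            rng_seed=0,
        )
        return preprocess_measurement(pair["VIS"], pair["NIR"])

    return _make


@pytest.fixture(scope="session")
def animal_dataset_small():
    """A compact two-stratum animal dataset shared across modeling tests."""
    return simulate_animal_dataset(n_per_class=30, rng_seed=11)
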
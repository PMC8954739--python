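import numpy as np
import pytest

from msidissect.io import MSIDataset, Spectrum
from msidissect.phantom import PhantomConfig, generate_phantom


@pytest.fixture
def tiny_dataset():
    """2x2 MALDI grid with simple handmade spectra (one pixel missing)."""
    spectra = {
        (0, 0): Spectrum([100.0, 200.0, 300.0], [2.0, 3.0, 5.0]),
        (0, 1): Spectrum([100.0, 200.0, 300.0], [1.0, 1.0, 2.0]),
        (1, 0): Spectrum([100.0, 200.0, 300.0], [4.0, 0.0, 0.0]),
    }
    return MSIDataset(
        modality="MALDI",
        pixel_size_um=10.0,
        grid_shape=(2, 2),
        spectra=spectra,
        metadata={"specimen_id": "S1", "animal_id": "A1", "timepoint_h": 1.0},
    )


@pytest.fixture(scope="session")
def small_config():
    """32x32 phantom geometry used across tests (fast to generate)."""
    return PhantomConfig(
        grid_shape=(32, 32), lumen_radius=5.0, mucosa_radius=9.0, outer_radius=14.0
    )


@pytest.fixture(scope="session")
def noiseless_phantom(small_config):
    """One noiseless section at 1 h post dose, with its ground truth."""
    return generate_phantom(small_config.noiseless(), 1.0, "S1", seed=42)


@pytest.fixture(scope="session")
def noisy_phantom(small_config):
    """One section at the default noise level, with its ground truth."""
    return generate_phantom(small_config, 1.0, "S1", seed=42)
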
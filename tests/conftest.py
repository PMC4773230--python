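import numpy as np
import pytest

from fibroscore.ct_io import CTVolume
from fibroscore.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A small two-lung phantom with moderate fibrotic content."""
    spec = PhantomSpec(grid_shape=(32, 48, 48), design_fibrotic_fraction=0.13, seed=11)
    return generate_phantom(spec)


@pytest.fixture
def random_volume():
    """Factory for random HU volumes spanning the full calibrated range."""

    def make(seed: int, shape=(8, 10, 12), spacing=(1.0, 1.0, 1.0)) -> CTVolume:
        rng = np.random.default_rng(seed)
        hu = rng.uniform(-1100, 400, size=shape)
        return CTVolume(voxels=hu, spacing_mm=spacing, patient_id=f"rand-{seed}")

    return make
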
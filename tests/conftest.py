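import numpy as np
import pytest

from miaclust import PhantomSpec, SegmentationConfig, Volume, make_phantom


@pytest.fixture(scope="session")
def small_coil():
    """A small, noisy wire-like phantom (shared across tests)."""
    spec = PhantomSpec(
        kind="plate_coil", shape=(32, 96, 96), thickness_vox=5,
        foreground_level=30000, background_level=0,
        gradient_amplitude=0.10, noise_sd=1500, seed=42, voxel_size_um=7.86,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def two_level_volume():
    """Noise-free two-material volume with a known labeling."""
    data = np.zeros((16, 16, 16), dtype=np.uint16)
    data[4:12, 4:12, 4:12] = 30000
    truth = np.where(data > 0, 2, 1).astype(np.int32)
    return Volume(data, voxel_size_um=5.0), truth


@pytest.fixture
def base_config():
    return SegmentationConfig(n_classes=2, grid_size=7, overlap_stride=4)
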
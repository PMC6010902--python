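import numpy as np
import pytest

from nanoholo import phantom
from nanoholo.volume import Volume3D


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def single_cell_phantom():
    """Centered 20-voxel sphere cell, no degradation."""
    spec = phantom.PhantomSpec(
        shape=(64, 64, 64),
        cells=[phantom.CellSpec(center=(32, 32, 32), radii=(20, 20, 20))],
        psf_sigma=0.0, noise_sigma=0.0)
    vol, labels = phantom.generate_tissue_phantom(spec)
    return spec, vol, labels


@pytest.fixture(scope="session")
def nested_cell_phantom():
    """Clean cell with visible nucleolus for region-growing tests."""
    spec = phantom.PhantomSpec(
        shape=(64, 64, 64),
        cells=[phantom.CellSpec(center=(32, 32, 32), radii=(22, 22, 22),
                                nucleolus_radius=5.0)],
        psf_sigma=0.0, noise_sigma=0.0)
    vol, labels = phantom.generate_tissue_phantom(spec)
    return vol, labels


@pytest.fixture()
def noisy_sphere():
    """Noisy bright sphere (contrast/noise = 5) plus ground truth."""
    rng = np.random.default_rng(7)
    img = np.full((40, 40, 40), 0.3, np.float32)
    zz, yy, xx = np.mgrid[0:40, 0:40, 0:40]
    truth = (zz - 20) ** 2 + (yy - 20) ** 2 + (xx - 20) ** 2 <= 12 ** 2
    img[truth] = 0.6
    img += rng.normal(0.0, 0.06, img.shape).astype(np.float32)
    return img, truth


def make_volume(arr, spacing=100.0):
    return Volume3D(np.asarray(arr), spacing=spacing)
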
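import numpy as np
import pytest

from droiq.phantoms import KSpaceGrid, build_disk_phantom, compound_kspace, realize


@pytest.fixture(scope="session")
def grid() -> KSpaceGrid:
    return KSpaceGrid(240.0, 128)


@pytest.fixture(scope="session")
def noiseless_disk_image():
    """Reference iFFT image of the default disk phantom (R=95, I=0.5), no noise."""
    spec = build_disk_phantom()
    return realize(spec)[1]


@pytest.fixture(scope="session")
def noisy_disk_images():
    """Six seeded realizations of the default disk phantom at sigma=0.04."""
    spec = build_disk_phantom(sigma=0.04, seed=101)
    noiseless = compound_kspace(spec.grid, spec.disks)
    return [realize(spec, k, noiseless)[1] for k in range(6)]


@pytest.fixture(scope="session")
def interior_mask(grid):
    ax = grid.pixel_axis()
    xx, yy = np.meshgrid(ax, ax)
    return np.hypot(xx, yy) < 80.0
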
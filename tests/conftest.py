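import pathlib
import sys

import numpy as np
import pytest

sys.path.insert(0, str(pathlib.Path(__file__).parent))

from tractdistill.geometry import VoxelGrid
from tractdistill.phantom import BundleSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_grid():
    return VoxelGrid.isotropic((16, 16, 16), 2.0)


@pytest.fixture(scope="session")
def straight_phantom(small_grid):
    """Single straight bundle along +x on a 16-voxel grid."""
    spec = BundleSpec.straight(
        (4.0, 15.0, 15.0), (26.0, 15.0, 15.0),
        radius_mm=2.5, n_streamlines=20, bundle_id=1,
    )
    return make_phantom([spec], small_grid, noise_sd=0.02, seed=7)


@pytest.fixture(scope="session")
def crossing_phantom(small_grid):
    """Two orthogonal straight bundles crossing near the grid center."""
    specs = [
        BundleSpec.straight((4.0, 15.0, 15.0), (26.0, 15.0, 15.0),
                            radius_mm=2.5, n_streamlines=15, bundle_id=1),
        BundleSpec.straight((15.0, 4.0, 15.0), (15.0, 26.0, 15.0),
                            radius_mm=2.5, n_streamlines=15, bundle_id=2),
    ]
    return make_phantom(specs, small_grid, noise_sd=0.02, seed=11)
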
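import numpy as np
import pytest

from salnet.grid import VoxelGrid


@pytest.fixture
def grid2mm():
    """32^3 voxel grid at 2 mm centered on the origin, full mask."""
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    aff[:3, 3] = -32.0
    return VoxelGrid(shape=(32, 32, 32), affine=aff)


@pytest.fixture
def grid1mm():
    """Small 1 mm grid for tracking tests."""
    aff = np.eye(4)
    aff[:3, 3] = -20.0
    return VoxelGrid(shape=(40, 40, 40), affine=aff)


def make_uniform_field(grid, direction, k=3):
    """OrientationField with one constant unit peak everywhere in the mask."""
    from salnet.tractography import OrientationField
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    peaks = np.zeros(grid.shape + (k, 3), dtype=np.float32)
    peaks[grid.mask, 0, :] = d
    return OrientationField(grid=grid, peaks=peaks)
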
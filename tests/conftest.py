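import numpy as np
import pytest

from planscore import DoseGrid, StructureMask, datasets


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def study_config():
    return datasets.load_study_config()


@pytest.fixture
def random_grid_factory(rng):
    """Factory for small random dose grids with a random non-empty mask."""

    def make(shape=(12, 10, 8), dose_scale=10.0, mask_p=0.5):
        dose = rng.uniform(0.0, dose_scale, size=shape)
        voxels = rng.random(shape) < mask_p
        if not voxels.any():
            voxels[tuple(np.array(shape) // 2)] = True
        grid = DoseGrid(dose=dose, spacing=(2.0, 2.5, 3.0))
        mask = StructureMask(name="S", role="oar", voxels=voxels)
        return grid, mask

    return make


def uniform_grid(value=2.0, shape=(6, 6, 6), spacing=(1.0, 1.0, 1.0)):
    grid = DoseGrid(dose=np.full(shape, float(value)), spacing=spacing)
    mask = StructureMask(name="U", role="target", voxels=np.ones(shape, dtype=bool))
    return grid, mask


def grid_from_doses(doses, spacing=(1.0, 1.0, 1.0)):
    """A 1 x 1 x n grid holding the given voxel doses, fully masked."""
    arr = np.asarray(doses, dtype=float).reshape(1, 1, -1)
    grid = DoseGrid(dose=arr, spacing=spacing)
    mask = StructureMask(name="L", role="oar", voxels=np.ones_like(arr, dtype=bool))
    return grid, mask
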
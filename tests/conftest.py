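import numpy as np
import pytest

from consenseg import BinaryMask, ImageGrid, SUVVolume


@pytest.fixture
def grid():
    """PET-like small grid: anisotropic 4 x 4 x 5 mm voxels."""
    return ImageGrid(shape=(12, 12, 8), spacing=(4.0, 4.0, 5.0))


@pytest.fixture
def mask_factory(grid):
    def make(indices=None, full_array=None, g=None):
        g = g or grid
        arr = np.zeros(g.shape, dtype=bool)
        if full_array is not None:
            arr = np.asarray(full_array, dtype=bool)
        elif indices is not None:
            for idx in indices:
                arr[tuple(idx)] = True
        return BinaryMask(g, arr)

    return make


@pytest.fixture
def volume_factory(grid):
    def make(values, g=None):
        g = g or grid
        return SUVVolume(g, np.asarray(values, dtype=np.float32))

    return make
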
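import numpy as np
import pytest

from synovolume import ImageVolume, SliceRange


@pytest.fixture
def toy_volume():
    """10x10x5 volume, spacing (0.5, 0.5, 1.0): voxel volume 0.25 mm^3."""
    rng = np.random.default_rng(42)
    data = rng.uniform(0, 100, size=(10, 10, 5))
    return ImageVolume(data=data, spacing=(0.5, 0.5, 1.0))


@pytest.fixture
def toy_range():
    return SliceRange(0, 4)


def make_volume(data, spacing=(1.0, 1.0, 1.0), slice_axis=2):
    return ImageVolume(data=np.asarray(data, dtype=float), spacing=spacing, slice_axis=slice_axis)
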
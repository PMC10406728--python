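import numpy as np
import pytest

from sliceloc.atlas import LabeledVolume
from sliceloc.frames import BrainFrame
from sliceloc.synthetic import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom():
    """Default full-size phantom volume and its structure graph."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_phantom():
    """Small phantom for cheap structural tests."""
    return make_phantom(PhantomSpec(shape_vox=(48, 40, 64), voxel_um=100.0))


@pytest.fixture()
def random_volume():
    """20^3 random-ID volume at 10 um voxels for slicing oracles."""
    rng = np.random.default_rng(1234)
    labels = rng.integers(0, 9, size=(20, 20, 20)).astype(np.int32)
    frame = BrainFrame(voxel_size_um=(10.0, 10.0, 10.0), shape_vox=(20, 20, 20))
    return LabeledVolume(labels=labels, frame=frame)
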
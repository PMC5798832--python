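import numpy as np
import pytest

from noduleomics import RoiPatch, fixture_microvolumes


def make_patch(voxels, mask=None, spacing=(1.0, 1.0, 1.0)) -> RoiPatch:
    voxels = np.asarray(voxels, dtype=float)
    if mask is None:
        mask = np.ones(voxels.shape, dtype=bool)
    return RoiPatch(voxels, mask, spacing)


@pytest.fixture(scope="session")
def micro_fixtures():
    return fixture_microvolumes()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_patch(rng):
    """5^3 random-intensity patch with an irregular but tight mask."""
    vox = rng.normal(50.0, 20.0, size=(5, 5, 5))
    mask = rng.random((5, 5, 5)) < 0.7
    # force tightness and non-emptiness
    mask[0, 0, 0] = mask[-1, -1, -1] = True
    return make_patch(vox, mask)
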
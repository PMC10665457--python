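import numpy as np
import pytest

from motionbayes.circular import DirectionGrid


@pytest.fixture(scope="session")
def grid():
    return DirectionGrid()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_voxel_dataset():
    """A compact synthetic voxel dataset shared across decoder tests."""
    from motionbayes import synth

    design = synth.make_design(6, seed=0)
    truth = synth.make_truth(n_voxels=80, seed=1)
    return synth.sample_voxel_patterns(design, truth, seed=2)
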
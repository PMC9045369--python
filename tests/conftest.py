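import numpy as np
import pytest

from petatn import BrainVolume, generate_atlas_phantom


@pytest.fixture(scope="session")
def atlas64():
    return generate_atlas_phantom((64, 64, 64), 2.0, seed=1)


@pytest.fixture(scope="session")
def atlas48():
    return generate_atlas_phantom((48, 48, 48), 2.0, seed=1)


@pytest.fixture(scope="session")
def atlas32():
    return generate_atlas_phantom((32, 32, 32), 2.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_volume(data, voxel=2.0, modality="PBB3"):
    affine = np.diag([voxel, voxel, voxel, 1.0])
    return BrainVolume(np.asarray(data, dtype=float), affine, "template", modality)
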
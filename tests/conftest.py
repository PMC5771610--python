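import numpy as np
import pytest

from tractmetrics import BinaryMask, ProbabilityMap, VoxelGrid


def make_mask(data, voxel_dims=(1.0, 1.0, 1.0), space_tag="test") -> BinaryMask:
    return BinaryMask(VoxelGrid(np.asarray(data, dtype=float), voxel_dims,
                                np.eye(4), space_tag))


def make_map(data, voxel_dims=(1.0, 1.0, 1.0), space_tag="test") -> ProbabilityMap:
    return ProbabilityMap(VoxelGrid(np.asarray(data, dtype=float), voxel_dims,
                                    np.eye(4), space_tag))


def random_masks(rng, n, shape=(8, 8, 8), p=0.3, voxel_dims=(1.0, 1.0, 1.0)):
    return [make_mask((rng.random(shape) < p).astype(float), voxel_dims) for _ in range(n)]


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
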
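import numpy as np
import pytest

from adpkd_metrics.core import LabelVolume, VoxelGrid


@pytest.fixture
def unit_grid():
    """10x10x10 grid at 1 mm isotropic."""
    return VoxelGrid(shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def random_label_volume():
    """Factory for random small label volumes with a complete registry."""

    def make(seed=0, shape=(12, 12, 12), spacing=(1.0, 1.5, 2.0), n_codes=3):
        rng = np.random.default_rng(seed)
        grid = VoxelGrid(shape=shape, spacing=spacing)
        codes = rng.integers(0, n_codes + 1, size=shape).astype(np.int32)
        registry = {c: f"organ{c}" for c in range(1, n_codes + 1)}
        return LabelVolume(grid=grid, codes=codes, registry=registry)

    return make
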
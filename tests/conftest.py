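import numpy as np
import pytest

from acinostereo import phantom


@pytest.fixture(scope="session")
def small_tree():
    return phantom.build_duct_tree(2, segment_length_um=40.0, radius_um=9.0, seed=1)


@pytest.fixture(scope="session")
def small_phantom(small_tree):
    """A depth-2 phantom with 8 alveoli at 1.48 um voxels, verified truth."""
    return phantom.synthesize_acinus(
        small_tree, n_alveoli=8, alveolus_radius_um=10.0, voxel_size_um=1.48, seed=2
    )


@pytest.fixture(scope="session")
def sphere_mask():
    """A voxelized ball, >= 40 voxels across, for Cavalieri design checks."""
    shape = (64, 64, 64)
    zz, yy, xx = np.indices(shape)
    return (zz - 32.0) ** 2 + (yy - 32.0) ** 2 + (xx - 32.0) ** 2 <= 26.0**2
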
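import numpy as np
import pytest

import rfdosim as rf
from rfdosim.phantoms import TissuePropertyTable


@pytest.fixture(scope="session")
def fixture_pair():
    """Canonical full-resolution reference/individual pair (2 mm voxels)."""
    return rf.make_fixture_pair(rf.PhantomRecipe(seed=0))


@pytest.fixture(scope="session")
def coarse_pair():
    """Same body at 4 mm voxels: cheap forward evaluations for pipeline tests."""
    return rf.make_fixture_pair(
        rf.PhantomRecipe(shape=(32, 32, 80), voxel_size=0.004, seed=0)
    )


@pytest.fixture(scope="session")
def coil():
    return rf.CoilField()


@pytest.fixture(scope="session")
def pose_dist():
    return rf.default_pose_distribution()


def make_property_table(sigma, rho, eps=None):
    """Tissue table with labels 1..n from parallel property arrays."""
    n = len(sigma)
    if eps is None:
        eps = [50.0] * n
    rows = [("Background", 0, 0.0, 1.0, 0.0)]
    for i in range(n):
        rows.append((f"tissue{i + 1}", i + 1, sigma[i], eps[i], rho[i]))
    return TissuePropertyTable.from_rows(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
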
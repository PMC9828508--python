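import numpy as np
import pytest

from atomgpr import oracle as orc
from atomgpr.alf import compute_alf


@pytest.fixture(scope="session")
def water_system():
    return orc.get_system("water")


@pytest.fixture(scope="session")
def ammonia_system():
    return orc.get_system("ammonia")


@pytest.fixture(scope="session")
def water_traj(water_system):
    geom, pes = water_system
    traj = orc.sample_configurations(orc.SamplerConfig(
        seed_geometry=geom, temperature=300.0, n_frames=120, seed=42))
    orc.label_trajectory(traj, pes)
    return traj


@pytest.fixture(scope="session")
def water_alf(water_traj):
    return compute_alf(water_traj[0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    """Haar-ish random proper rotation matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
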
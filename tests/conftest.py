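import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import patchdose as pdx

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def y90_spectrum():
    return pdx.BetaSpectrum.yttrium90()


@pytest.fixture(scope="session")
def water_table():
    return pdx.StoppingPowerTable.water()


@pytest.fixture(scope="session")
def patient():
    """Synthetic SIRT patient on the full SPECT grid (seeded, deterministic)."""
    return pdx.make_synthetic_patient(pdx.PhantomSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def uniform_water(shape=(16, 16, 16), voxel_mm=4.0):
    return pdx.VoxelGrid(np.ones(shape), (voxel_mm,) * 3, role="density")


def point_source(shape=(16, 16, 16), voxel_mm=4.0, at=None):
    v = np.zeros(shape)
    at = at or tuple(s // 2 for s in shape)
    v[at] = 1.0
    return pdx.VoxelGrid(v, (voxel_mm,) * 3, role="TIA")
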
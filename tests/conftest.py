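import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rhizopet as rp
from rhizopet import acquisition

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


#: compact phantom for fast acquisition/quantify tests: two 35-voxel axial
#: windows with a 25-voxel shift, two nodules
SMALL_PHANTOM_CFG = rp.PhantomConfig(
    grid_shape=(25, 25, 60),
    n_nodules=2,
    n_laterals=20,
    lateral_length_range_mm=(8.0, 18.0),
    pedicel_length_range_mm=(4.0, 6.0),
    window_voxels=35,
    offset_voxels=25,
    edge_margin_voxels=2,
)

SMALL_ACQ_CFG = rp.AcquisitionConfig(window_voxels=35, offset_voxels=25, seed=7)


@pytest.fixture(scope="session")
def small_phantom():
    return rp.build_phantom(SMALL_PHANTOM_CFG, seed=7)


@pytest.fixture(scope="session")
def small_model(small_phantom):
    return rp.build_kinetics(small_phantom, rp.KineticsConfig(), seed=7)


@pytest.fixture(scope="session")
def small_acq_cfg():
    return SMALL_ACQ_CFG


@pytest.fixture(scope="session")
def small_session(small_phantom, small_model, small_acq_cfg):
    """One noisy 22-frame session of the compact phantom."""
    return acquisition.simulate_session(small_phantom, small_model, 1, small_acq_cfg)


def single_voxel_phantom(weight: float = 1.0, voxel=(2, 2, 2), grid=(5, 5, 10)):
    """Minimal phantom: one nodule occupying exactly one voxel."""
    label = np.zeros(grid, dtype=np.int32)
    label[voxel] = 1
    center = tuple((i + 0.5) * 1.15 for i in voxel)
    spec = rp.StructureSpec(1, rp.NODULE, ("sphere", center, 0.5), weight)
    return rp.RootPhantom(grid, 1.15, label, [spec])
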
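import numpy as np
import pytest

from smsepi.encode import AcquisitionParams, encode_acquisition
from smsepi.phantom import build_coil_maps, build_phantom, default_phantom_spec
from smsepi.plan import plan

PAPER_TES = (9.0, 21.5, 34.0)


@pytest.fixture(scope="session")
def plan_mb4():
    """64x64, 8 slices in 2 groups of MB=4, FOV/4 shift, 4 segments."""
    return plan(n_pe=64, n_segments=4, n_slices=8, mb=4, f=4,
                te_list=PAPER_TES, tr=261.0)


@pytest.fixture(scope="session")
def phantom_mb4():
    return build_phantom(default_phantom_spec(grid_shape=(8, 64, 64)))


@pytest.fixture(scope="session")
def coils_mb4():
    return build_coil_maps(8, (64, 64), seed=3, n_slices=8)


@pytest.fixture(scope="session")
def sb_mb4(plan_mb4, phantom_mb4, coils_mb4):
    par = AcquisitionParams.from_plan(plan_mb4)
    return encode_acquisition(phantom_mb4, coils_mb4, plan_mb4, par, sms=False)


@pytest.fixture(scope="session")
def sms_mb4(plan_mb4, phantom_mb4, coils_mb4):
    par = AcquisitionParams.from_plan(plan_mb4)
    return encode_acquisition(phantom_mb4, coils_mb4, plan_mb4, par, sms=True)


@pytest.fixture(scope="session")
def plan_mb2():
    """Small 2-slice MB=2 setup on a 32x32 grid (f=2, 2 segments)."""
    return plan(n_pe=32, n_segments=2, n_slices=2, mb=2, f=2,
                te_list=PAPER_TES, tr=261.0)


@pytest.fixture(scope="session")
def phantom_mb2():
    return build_phantom(default_phantom_spec(grid_shape=(2, 32, 32)))


@pytest.fixture(scope="session")
def coils_mb2():
    return build_coil_maps(4, (32, 32), seed=11, n_slices=2)


@pytest.fixture(scope="session")
def sb_mb2(plan_mb2, phantom_mb2, coils_mb2):
    par = AcquisitionParams.from_plan(plan_mb2)
    return encode_acquisition(phantom_mb2, coils_mb2, plan_mb2, par, sms=False)
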
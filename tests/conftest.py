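import numpy as np
import pytest

from dcequant.core import AcquisitionSpec
from dcequant.synthetic import DROGrid, generate_dro_phantom, generate_vif


@pytest.fixture(scope="session")
def spec():
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def cp_curve(spec):
    """The default synthetic plasma curve on the default time grid."""
    return generate_vif(spec)


@pytest.fixture(scope="session")
def small_dro():
    """Compact noiseless reference-object study (81 voxels, full time grid).

    3 Ktrans x 2 ve patches of 3x3 voxels plus a 3-row vessel strip; small
    enough that every test needing a full forward-modelled study stays fast.
    """
    grid = DROGrid(
        ktrans_values=(0.02, 0.1, 0.35),
        ve_values=(0.1, 0.5),
        vp=0.05,
        patch_shape=(3, 3),
        vessel_rows=3,
    )
    return generate_dro_phantom(grid=grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
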
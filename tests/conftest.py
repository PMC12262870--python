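import numpy as np
import pytest

from sinconn.maps import ROIGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_roi():
    """8x8x8 grid, 2 mm voxels — big enough for a bump, fast to simulate."""
    return ROIGeometry.default_grid(name="LPrCGsup", shape=(8, 8, 8),
                                    voxel_mm=2.0, width_mm=6.0)


@pytest.fixture
def default_roi():
    """The 12x12x12, 2 mm default grid."""
    return ROIGeometry.default_grid(name="RSMA")
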
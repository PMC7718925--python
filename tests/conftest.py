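import numpy as np
import pytest

from hessrad import RoiMask, Volume3D


def quadratic_volume(form, n=24, spacing=1.0):
    """Volume sampling a quadratic form of world-mm coordinates, grid-centered."""
    idx = np.indices((n, n, n), dtype=np.float64) - (n - 1) / 2.0
    x, y, z = (idx[i] * spacing for i in range(3))
    return Volume3D(form(x, y, z), (spacing,) * 3)


@pytest.fixture
def small_roi():
    """A 4-level 5x5x5 quantized ROI with an ellipsoidal mask (seeded)."""
    rng = np.random.default_rng(11)
    q = rng.integers(0, 4, size=(5, 5, 5))
    mask = np.ones((5, 5, 5), dtype=bool)
    mask[0, 0, 0] = mask[4, 4, 4] = False
    return Volume3D(q), RoiMask(mask)


@pytest.fixture
def interior_roi_volume():
    """Smooth random volume with a small interior ROI, away from all borders."""
    rng = np.random.default_rng(7)
    from scipy import ndimage

    data = ndimage.gaussian_filter(rng.normal(0, 100, (32, 32, 32)), 2.0)
    mask = np.zeros((32, 32, 32), dtype=bool)
    mask[12:20, 12:20, 12:20] = True
    return Volume3D(data), RoiMask(mask)
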
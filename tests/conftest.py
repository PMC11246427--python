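import numpy as np
import pandas as pd
import pytest

from micropat import FieldImage


def stripe_image(angle_deg: float, shape=(128, 128), period_px: float = 12.0) -> np.ndarray:
    """Sinusoidal stripes oriented at ``angle_deg`` (CCW from +x, y up)."""
    th = np.radians(angle_deg)
    nx, ny_up = -np.sin(th), np.cos(th)
    r, c = np.mgrid[0 : shape[0], 0 : shape[1]]
    phase = (c * nx + (-r) * ny_up) * 2 * np.pi / period_px
    return np.cos(phase)


def disjoint_grid_cells(n_side: int, pitch_um: float, radius_um: float, px_size_um: float) -> pd.DataFrame:
    """Cells on a regular grid, guaranteed non-touching."""
    coords = (np.arange(n_side) + 0.5) * pitch_um
    xx, yy = np.meshgrid(coords, coords)
    n = n_side * n_side
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "x_um": xx.ravel(),
            "y_um": yy.ravel(),
            "radius_um": np.full(n, radius_um),
        }
    )


@pytest.fixture
def stripes30():
    return stripe_image(30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_image():
    return FieldImage({"flat": np.full((32, 32), 7.0)}, px_size_um=2.0)
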
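import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from wfm.core_io import Grid2D, VectorField2D


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def force_grid():
    return Grid2D(nx=26, ny=26, pixel_size=3.44)


def smooth_balanced_field(grid: Grid2D, rng, scale=100.0, sigma=2.0, mode="wrap"):
    """Zero-mean, band-limited random traction field on `grid`."""
    cx = gaussian_filter(rng.normal(size=grid.shape), sigma, mode=mode)
    cy = gaussian_filter(rng.normal(size=grid.shape), sigma, mode=mode)
    cx -= cx.mean()
    cy -= cy.mean()
    peak = max(np.abs(cx).max(), np.abs(cy).max())
    return VectorField2D(grid, cx * scale / peak, cy * scale / peak, units="Pa")


@pytest.fixture
def balanced_field(force_grid, rng):
    return smooth_balanced_field(force_grid, rng)


def rel_l2(a: VectorField2D, b: VectorField2D) -> float:
    num = np.sqrt(np.sum((a.comp_x - b.comp_x) ** 2 + (a.comp_y - b.comp_y) ** 2))
    den = np.sqrt(np.sum(b.comp_x**2 + b.comp_y**2))
    return float(num / den)
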
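import numpy as np
import pytest

from agroclim import LatLonGrid, PentadClimatology
from agroclim.synthetic import SyntheticScenarioSpec


@pytest.fixture
def small_grid():
    """Coarse 2-degree grid over 40..80N, a 20-degree lon window."""
    return LatLonGrid(np.arange(41.0, 80.0, 2.0), np.arange(-9.0, 11.0, 2.0), 2.0)


@pytest.fixture
def band_grid():
    """0.5-degree strip over 30..75N, 5-degree lon window (fast, full res)."""
    return LatLonGrid(np.arange(30.25, 75.0, 0.5), np.arange(0.25, 5.0, 0.5), 0.5)


@pytest.fixture
def noise_free_spec(small_grid):
    return SyntheticScenarioSpec(
        grid=small_grid,
        baseline_mean_at_equator=22.0,
        lat_gradient=-0.5,
        seasonal_amplitude=10.0,
        warming_rate=0.6,
        model_offsets=(0.5, -0.5),
        model_trend_factors=(1.2, 0.8),
        noise_sd=0.0,
        seed=7,
    )


def make_clim(grid, monthly, label_year=2049, variable="temperature"):
    """Pentad climatology from a (12,) profile or full (12, nlat, nlon) array."""
    monthly = np.asarray(monthly, dtype=float)
    if monthly.ndim == 1:
        monthly = np.broadcast_to(monthly[:, None, None], (12, *grid.shape)).copy()
    return PentadClimatology(grid, label_year, (label_year - 4, label_year), monthly, variable)
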
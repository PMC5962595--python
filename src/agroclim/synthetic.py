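"""Pseudo-GCM synthetic climate: seeded monthly/daily series and region masks.

The temperature model is deliberately simple and fully analytic so that
pipeline behaviour can be predicted in closed form:

    T(cell, y, m) = T0 + g*|lat| + A*cos(2*pi*(m - 7)/12)*s(lat)
                    + w * f_i * (y - start_year)/10 + b_i + eps

with hemisphere sign s(lat) = +1 for lat >= 0 (July peak) and -1 south
(January peak), per-model trend factor f_i and offset b_i, and iid
Gaussian noise eps. Precipitation is a latitude- and season-shaped
positive field clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import LatLonGrid, MonthlyClimateSeries, RegionMask

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MONTH_START = np.concatenate([[0], np.cumsum(DAYS_IN_MONTH)])  # day-of-year offsets


@dataclass
class SyntheticScenarioSpec:
    """Parameters of a pseudo-ensemble climate scenario.

    ``model_offsets`` (mean ~0) and ``model_trend_factors`` must have equal
    length: that length is the pseudo-ensemble size.
    """

    grid: LatLonGrid
    baseline_mean_at_equator: float = 22.0  # degC
    lat_gradient: float = -0.6  # degC per degree latitude (negative northward)
    seasonal_amplitude: float = 12.0  # degC
    warming_rate: float = 0.5  # degC per decade
    model_offsets: tuple = (0.0,)
    model_trend_factors: tuple = (1.0,)
    noise_sd: float = 0.0
    precip_base: float = 60.0  # mm/month
    precip_lat_shape: tuple = (40.0, 25.0)  # (peak lat |deg|, gaussian width deg)
    precip_season_amp: float = 0.3
    seed: int = 0

    def __post_init__(self):
        self.model_offsets = tuple(float(x) for x in self.model_offsets)
        self.model_trend_factors = tuple(float(x) for x in self.model_trend_factors)
        if len(self.model_offsets) != len(self.model_trend_factors):
            raise ValueError("model_offsets and model_trend_factors must have equal length")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")

    @property
    def n_models(self) -> int:
        return len(self.model_offsets)


def _substream(spec: SyntheticScenarioSpec, model_index: int, variable: str, year: int):
    """Deterministic per-(model, variable, year) random substream."""
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=spec.seed,
            spawn_key=(model_index, {"temperature": 0, "precipitation": 1, "daily": 2}[variable], year),
        )
    )


def _check_model_years(spec, model_index, start_year, end_year):
    if not 0 <= model_index < spec.n_models:
        raise IndexError(f"model_index {model_index} outside ensemble of {spec.n_models}")
    if end_year < start_year:
        raise ValueError("end_year must be >= start_year")


def _mean_temperature(spec, model_index, month, year, start_year):
    """Noise-free monthly-mean temperature field, shape (n_lat, n_lon)."""
    lat = spec.grid.lat[:, None]
    hemi = np.where(lat >= 0, 1.0, -1.0)
    t = (
        spec.baseline_mean_at_equator
        + spec.lat_gradient * np.abs(lat)
        + spec.seasonal_amplitude * np.cos(2 * np.pi * (month - 7) / 12.0) * hemi
        + spec.warming_rate
        * spec.model_trend_factors[model_index]
        * (year - start_year)
        / 10.0
        + spec.model_offsets[model_index]
    )
    return np.broadcast_to(t, spec.grid.shape).copy()


def generate_temperature_series(
    spec: SyntheticScenarioSpec, model_index: int, start_year: int, end_year: int
) -> MonthlyClimateSeries:
    """Monthly temperature for one pseudo-model over [start_year, end_year]."""
    _check_model_years(spec, model_index, start_year, end_year)
    times, frames = [], []
    for year in range(start_year, end_year + 1):
        rng = _substream(spec, model_index, "temperature", year)
        for month in range(1, 13):
            t = _mean_temperature(spec, model_index, month, year, start_year)
            if spec.noise_sd > 0:
                t = t + rng.normal(0.0, spec.noise_sd, size=t.shape)
            times.append((year, month))
            frames.append(t)
    return MonthlyClimateSeries(spec.grid, "temperature", times, np.stack(frames))


def _mean_precipitation(spec, month):
    peak, width = spec.precip_lat_shape
    lat = spec.grid.lat[:, None]
    hemi = np.where(lat >= 0, 1.0, -1.0)
    shape = np.exp(-0.5 * ((np.abs(lat) - peak) / width) ** 2)
    seasonal = 1.0 + spec.precip_season_amp * np.cos(2 * np.pi * (month - 7) / 12.0) * hemi
    p = spec.precip_base * shape * seasonal
    return np.broadcast_to(p, spec.grid.shape).copy()


def generate_precipitation_series(
    spec: SyntheticScenarioSpec, model_index: int, start_year: int, end_year: int
) -> MonthlyClimateSeries:
    """Monthly precipitation (mm/month), nonnegative, seeded."""
    _check_model_years(spec, model_index, start_year, end_year)
    times, frames = [], []
    for year in range(start_year, end_year + 1):
        rng = _substream(spec, model_index, "precipitation", year)
        for month in range(1, 13):
            p = _mean_precipitation(spec, month)
            if spec.noise_sd > 0:
                p = p + rng.normal(0.0, spec.noise_sd, size=p.shape)
            times.append((year, month))
            frames.append(np.maximum(p, 0.0))
    return MonthlyClimateSeries(spec.grid, "precipitation", times, np.stack(frames))


def generate_daily_temperature(
    spec: SyntheticScenarioSpec,
    model_index: int,
    year: int,
    start_year: int | None = None,
    constant_within_month: bool = False,
) -> np.ndarray:
    """Daily temperatures for one year, shape (365, n_lat, n_lon).

    The daily curve is the seasonal sinusoid sampled at day resolution and
    then recentred month-by-month so that each calendar-month mean equals
    the monthly-series value exactly (noise off). With
    ``constant_within_month=True`` every day simply repeats its month's
    value, making the days-per-month GDD approximation exact.

    ``start_year`` anchors the warming trend; defaults to ``year``
    (zero accumulated trend).
    """
    if start_year is None:
        start_year = year
    _check_model_years(spec, model_index, start_year, max(year, start_year))
    lat = spec.grid.lat[:, None]
    hemi = np.where(lat >= 0, 1.0, -1.0)
    monthly = np.stack(
        [_mean_temperature(spec, model_index, m, year, start_year) for m in range(1, 13)]
    )
    daily = np.empty((365, *spec.grid.shape))
    if constant_within_month:
        for m in range(12):
            daily[_MONTH_START[m] : _MONTH_START[m + 1]] = monthly[m]
        return daily
    # July 16 (doy 197) is the sinusoid peak, matching the monthly cos((m-7)/12) phase
    days = np.arange(1, 366)[:, None, None]
    cyc = spec.seasonal_amplitude * np.cos(2 * np.pi * (days - 197) / 365.0) * hemi[None]
    base = (
        spec.baseline_mean_at_equator
        + spec.lat_gradient * np.abs(lat)[None]
        + spec.warming_rate * spec.model_trend_factors[model_index] * (year - start_year) / 10.0
        + spec.model_offsets[model_index]
    )
    daily = np.broadcast_to(base + cyc, (365, *spec.grid.shape)).copy()
    for m in range(12):
        sl = slice(_MONTH_START[m], _MONTH_START[m + 1])
        daily[sl] += monthly[m] - daily[sl].mean(axis=0)
    return daily


def generate_region_masks(
    grid: LatLonGrid,
    boreal_band: tuple[float, float],
    n_countries: int,
    seed: int = 0,
    split_meridian: float = -30.0,
) -> list[RegionMask]:
    """Pseudo-boreal band mask, country sector masks partitioning it, and two
    continent masks splitting it at ``split_meridian``.

    Returns ``[boreal, country_0..country_{n-1}, continent_west, continent_east]``.
    Countries are contiguous longitude sectors with seeded random boundaries;
    their union is exactly the boreal mask and they are pairwise disjoint.
    """
    lat_min, lat_max = boreal_band
    if lat_min >= lat_max:
        raise ValueError("boreal_band must satisfy lat_min < lat_max")
    if n_countries < 1:
        raise ValueError("n_countries must be >= 1")
    in_band = (grid.lat >= lat_min) & (grid.lat < lat_max)
    if not in_band.any():
        raise ValueError("boreal band contains no grid latitudes")
    boreal = np.zeros(grid.shape, dtype=bool)
    boreal[in_band, :] = True
    masks = [RegionMask("boreal", grid, boreal)]

    nlon = grid.lon.size
    rng = np.random.default_rng(seed)
    if n_countries >= nlon:
        raise ValueError("n_countries must be smaller than the number of longitude columns")
    cuts = np.sort(rng.choice(np.arange(1, nlon), size=n_countries - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [nlon]])
    for i in range(n_countries):
        m = np.zeros(grid.shape, dtype=bool)
        m[in_band, bounds[i] : bounds[i + 1]] = True
        masks.append(RegionMask(f"country_{i}", grid, m))

    west = np.zeros(grid.shape, dtype=bool)
    west[in_band, :] = grid.lon[None, :] < split_meridian
    east = boreal & ~west
    masks.append(RegionMask("continent_west", grid, west))
    masks.append(RegionMask("continent_east", grid, east))
    return masks
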
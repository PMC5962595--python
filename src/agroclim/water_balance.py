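"""Day length, Thornthwaite potential evapotranspiration, and seasonal water balance.

Day length uses the standard solar declination / sunset hour-angle closed
form with declination 23.44 deg * sin(2*pi*(284 + n)/365); the arccos
argument is clamped so polar day and polar night come out as exactly 24 h
and 0 h.

PET is the classic Thornthwaite formula (uncorrected, no hot-month
variant): monthly PET = 16 * (L/12) * (N/30) * (10*T/I)^a mm for months
with T > 0 degC, else 0, with annual heat index
I = sum over months T > 0 of (T/5)^1.514 and
a = 6.75e-7*I^3 - 7.71e-5*I^2 + 1.792e-2*I + 0.49239.
Day lengths enter through the monthly mean L at the cell's latitude
snapped to the nearest 5 degrees by default (exact-latitude mode
available), which reproduces the banded appearance of PET maps built on
discrete latitude intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gdd import DAYS_IN_MONTH, PentadClimatology
from .grids import LatLonGrid

_MONTH_START = np.concatenate([[0], np.cumsum(DAYS_IN_MONTH)])
DEFAULT_SEASON = (5, 6, 7, 8, 9, 10)  # May through October
ARIDITY_THRESHOLD = 0.65


def day_length(lat, day_of_year) -> np.ndarray | float:
    """Hours of daylight at latitude ``lat`` (deg) on ``day_of_year`` (1..365).

    Vectorized over both arguments. Clamping of -tan(phi)*tan(delta) to
    [-1, 1] yields 24 h (polar day) and 0 h (polar night) beyond the polar
    circles.
    """
    lat_arr = np.asarray(lat, dtype=float)
    day_arr = np.asarray(day_of_year)
    if np.any(np.abs(lat_arr) > 90):
        raise ValueError("latitude must be within [-90, 90]")
    if np.any((day_arr < 1) | (day_arr > 365)):
        raise ValueError("day_of_year must be within [1, 365]")
    decl = np.radians(23.44) * np.sin(2 * np.pi * (284 + day_arr) / 365.0)
    x = np.clip(-np.tan(np.radians(lat_arr)) * np.tan(decl), -1.0, 1.0)
    hours = (24.0 / np.pi) * np.arccos(x)
    return hours if hours.ndim else float(hours)


@dataclass
class DayLengthTable:
    """Day length (hours) per (latitude, day-of-year 1..365)."""

    latitudes: np.ndarray
    hours: np.ndarray  # (n_lat, 365)

    @classmethod
    def build(cls, latitudes) -> "DayLengthTable":
        lats = np.asarray(latitudes, dtype=float)
        days = np.arange(1, 366)
        hours = day_length(lats[:, None], days[None, :])
        return cls(lats, hours)

    @classmethod
    def five_degree(cls, lat_min: float = -90.0, lat_max: float = 90.0) -> "DayLengthTable":
        lo = int(np.floor(lat_min / 5.0)) * 5
        hi = int(np.ceil(lat_max / 5.0)) * 5
        return cls.build(np.arange(lo, hi + 1, 5.0))

    def monthly_mean(self) -> np.ndarray:
        """Mean day length per (latitude, month)."""
        out = np.empty((self.latitudes.size, 12))
        for m in range(12):
            out[:, m] = self.hours[:, _MONTH_START[m] : _MONTH_START[m + 1]].mean(axis=1)
        return out

    def row_for(self, lat: float) -> int:
        return int(np.argmin(np.abs(self.latitudes - lat)))


@dataclass
class PETField:
    grid: LatLonGrid
    label_year: int
    pet: np.ndarray  # mm per (12, n_lat, n_lon)
    heat_index: np.ndarray  # I per cell
    exponent: np.ndarray  # a per cell


def thornthwaite_pet(
    clim: PentadClimatology,
    day_lengths: DayLengthTable | None = None,
    snap_latitude: bool = True,
) -> PETField:
    """Monthly Thornthwaite PET for a temperature pentad climatology.

    ``snap_latitude=True`` (default) uses the day-length row nearest each
    cell's latitude — with the default 5-degree table this is the nearest
    5-degree multiple. Pass a dense table and ``snap_latitude=False``-style
    usage by building the table at the grid latitudes for exact mode.
    """
    if clim.variable != "temperature":
        raise ValueError("thornthwaite_pet requires a temperature climatology")
    grid = clim.grid
    if day_lengths is None:
        if snap_latitude:
            day_lengths = DayLengthTable.five_degree(grid.lat.min(), grid.lat.max())
        else:
            day_lengths = DayLengthTable.build(grid.lat)
    L_monthly = day_lengths.monthly_mean()  # (n_table_lat, 12)
    rows = np.array([day_lengths.row_for(phi) for phi in grid.lat])
    L = L_monthly[rows]  # (n_lat, 12)

    t = clim.monthly_mean  # (12, n_lat, n_lon)
    warm = np.where(np.isnan(t), np.nan, np.maximum(t, 0.0))
    with np.errstate(invalid="ignore"):
        heat_terms = np.where(warm > 0, (warm / 5.0) ** 1.514, 0.0)
    heat_terms = np.where(np.isnan(warm), np.nan, heat_terms)
    I = heat_terms.sum(axis=0)  # NaN propagates from missing months
    a = 6.75e-7 * I**3 - 7.71e-5 * I**2 + 1.792e-2 * I + 0.49239

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(I > 0, 10.0 * np.maximum(t, 0.0) / I, 0.0)
        core = 16.0 * np.power(ratio, a)
    factors = (L.T[:, :, None] / 12.0) * (DAYS_IN_MONTH[:, None, None] / 30.0)
    pet = np.where(t > 0, core * factors, 0.0)
    pet = np.where(np.isnan(t) | np.isnan(I), np.nan, pet)
    return PETField(grid, clim.label_year, pet, I, a)


@dataclass
class WaterBalanceBundle:
    """Growing-season precipitation, PET, their difference, and p/PET aridity."""

    grid: LatLonGrid
    label_year: int
    seasonal_precip: np.ndarray  # mm
    seasonal_pet: np.ndarray  # mm
    balance: np.ndarray  # mm, precip - pet
    aridity_index: np.ndarray  # p/PET, NaN where seasonal PET == 0
    months: tuple = DEFAULT_SEASON
    monthly_balance: np.ndarray | None = None  # (n_months, n_lat, n_lon)


def seasonal_water_balance(
    precip_clim: PentadClimatology,
    pet: PETField,
    months: tuple = DEFAULT_SEASON,
) -> WaterBalanceBundle:
    """Seasonal sums of P and PET over ``months``, balance P - PET, and p/PET."""
    if precip_clim.variable != "precipitation":
        raise ValueError("seasonal_water_balance requires a precipitation climatology")
    if len(months) == 0:
        raise ValueError("month list must not be empty")
    if precip_clim.grid != pet.grid or precip_clim.label_year != pet.label_year:
        raise ValueError("precipitation and PET must share grid and label_year")
    idx = [m - 1 for m in months]
    p_season = precip_clim.monthly_mean[idx].sum(axis=0)
    pet_season = pet.pet[idx].sum(axis=0)
    balance = p_season - pet_season
    with np.errstate(invalid="ignore", divide="ignore"):
        aridity = np.where(pet_season > 0, p_season / np.where(pet_season > 0, pet_season, 1), np.nan)
    monthly_balance = precip_clim.monthly_mean[idx] - pet.pet[idx]
    return WaterBalanceBundle(
        precip_clim.grid,
        precip_clim.label_year,
        p_season,
        pet_season,
        balance,
        aridity,
        tuple(months),
        monthly_balance,
    )


def classify_aridity(bundle: WaterBalanceBundle, threshold: float = ARIDITY_THRESHOLD) -> np.ndarray:
    """Arid-side classification: True where p/PET < threshold; NaN preserved.

    Returns a float array with values {0.0, 1.0, NaN} so missing cells stay
    distinguishable from not-arid.
    """
    idx = bundle.aridity_index
    out = np.full(idx.shape, np.nan)
    ok = ~np.isnan(idx)
    out[ok] = (idx[ok] < threshold).astype(float)
    return out


def photoperiod_profile(latitudes, months: tuple = (5, 6, 7, 8, 9)) -> dict:
    """(min, max, mean) day length over the given months per latitude.

    Default window is May through September.
    """
    lats = np.asarray(latitudes, dtype=float)
    days = np.concatenate(
        [np.arange(_MONTH_START[m - 1] + 1, _MONTH_START[m] + 1) for m in months]
    )
    hours = day_length(lats[:, None], days[None, :])
    return {
        "latitudes": lats,
        "min": hours.min(axis=1),
        "max": hours.max(axis=1),
        "mean": hours.mean(axis=1),
    }
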
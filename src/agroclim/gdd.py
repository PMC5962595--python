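"""Pentad climatologies, annual growing degree days, and feasibility masks.

GDD accumulation uses monthly means with days-per-month multipliers on a
fixed 365-day (no-leap) calendar: months whose mean exceeds the base
temperature contribute ``(mean - t_base) * days_in_month``; no upper cap.
Month inclusion is strict (``> t_base``); the feasibility threshold is
inclusive (``gdd >= threshold``).

Accuracy of the monthly approximation: for daily series constant within
each month it is exact. For a smooth sinusoidal annual cycle of amplitude
A (degC) the discrepancy against the true daily sum is concentrated in
months whose daily range straddles the base temperature; empirically the
per-cell error stays below 4.2 * A degC*day and shrinks linearly as the
within-month variation shrinks (see the oracle-equivalence tests for the
measured bound).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import LatLonGrid, MonthlyClimateSeries

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

DEFAULT_T_BASE = 5.0
DEFAULT_THRESHOLD = 1200.0


@dataclass
class PentadClimatology:
    """Twelve month-wise means over a 5-year window, labelled by its end year."""

    grid: LatLonGrid
    label_year: int
    window: tuple[int, int]
    monthly_mean: np.ndarray  # (12, n_lat, n_lon), NaN = missing
    variable: str

    def __post_init__(self):
        start, end = self.window
        if end - start != 4:
            raise ValueError("pentad window must span exactly 5 calendar years")
        if self.label_year != end:
            raise ValueError("label_year must equal the window end year")
        self.monthly_mean = np.asarray(self.monthly_mean, dtype=float)
        if self.monthly_mean.shape != (12, *self.grid.shape):
            raise ValueError("monthly_mean must have shape (12, n_lat, n_lon)")


@dataclass
class GDDField:
    grid: LatLonGrid
    label_year: int
    gdd: np.ndarray  # degC*day per cell, NaN = missing
    t_base: float = DEFAULT_T_BASE

    def __post_init__(self):
        self.gdd = np.asarray(self.gdd, dtype=float)
        ok = ~np.isnan(self.gdd)
        if ok.any() and self.gdd[ok].min() < 0:
            raise ValueError("gdd must be nonnegative where not missing")


@dataclass
class FeasibilityMask:
    grid: LatLonGrid
    label_year: int
    feasible: np.ndarray  # bool; missing cells are always False
    missing: np.ndarray  # bool
    threshold: float = DEFAULT_THRESHOLD


def pentad_average(series: MonthlyClimateSeries, label_year: int) -> PentadClimatology:
    """Average each calendar month over the window [label_year-4, label_year].

    A cell missing in any of a month's five values is missing for that
    month (strict propagation).
    """
    start = label_year - 4
    wanted = [(y, m) for y in range(start, label_year + 1) for m in range(1, 13)]
    have = set(series.times)
    absent = [t for t in wanted if t not in have]
    if absent:
        names = ", ".join(f"{y}-{m:02d}" for y, m in absent[:6])
        more = "" if len(absent) <= 6 else f" (+{len(absent) - 6} more)"
        raise ValueError(f"pentad {start}-{label_year} incomplete: missing {names}{more}")
    monthly = np.empty((12, *series.grid.shape))
    for m in range(1, 13):
        idx = [series.time_index(y, m) for y in range(start, label_year + 1)]
        monthly[m - 1] = series.values[idx].mean(axis=0)  # NaN propagates
    return PentadClimatology(series.grid, label_year, (start, label_year), monthly, series.variable)


def annual_gdd(clim: PentadClimatology, t_base: float = DEFAULT_T_BASE) -> GDDField:
    """Annual GDD from monthly means: sum over months with mean > t_base of
    (mean - t_base) * days_in_month; no upper temperature cap."""
    if clim.variable != "temperature":
        raise ValueError("annual_gdd requires a temperature climatology")
    t = clim.monthly_mean
    contrib = np.where(t > t_base, (t - t_base) * DAYS_IN_MONTH[:, None, None], 0.0)
    contrib = np.where(np.isnan(t), np.nan, contrib)
    gdd = contrib.sum(axis=0)  # any missing month -> NaN
    return GDDField(clim.grid, clim.label_year, gdd, t_base)


def feasibility(gdd: GDDField, threshold: float = DEFAULT_THRESHOLD) -> FeasibilityMask:
    """Inclusive threshold mask; missing gdd -> not feasible, flagged missing."""
    missing = np.isnan(gdd.gdd)
    feasible = np.zeros(gdd.gdd.shape, dtype=bool)
    feasible[~missing] = gdd.gdd[~missing] >= threshold
    return FeasibilityMask(gdd.grid, gdd.label_year, feasible, missing, threshold)


def gdd_difference(later: GDDField, earlier: GDDField) -> np.ndarray:
    """Cellwise later - earlier (degC*day); missing in either -> NaN."""
    if later.grid != earlier.grid:
        raise ValueError("gdd_difference requires matching grids")
    if later.label_year <= earlier.label_year:
        raise ValueError("'later' must have a later label_year than 'earlier'")
    return later.gdd - earlier.gdd


def daily_gdd_sum(daily: np.ndarray, t_base: float = DEFAULT_T_BASE) -> np.ndarray:
    """Oracle: sum of max(T_d - t_base, 0) over a (365, ...) daily array."""
    daily = np.asarray(daily, dtype=float)
    if daily.shape[0] != 365:
        raise ValueError("daily array must have 365 leading entries")
    return np.maximum(daily - t_base, 0.0).sum(axis=0)
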
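"""Area accounting over regions and latitude bands, and leading-edge shifts.

All areas are reported in 1e6 km^2. Percentages reproduce printed-table
arithmetic with round-half-up at the printed precision (``round_half_up``).
Northward shift distances are meridional arc lengths: degrees of latitude
times pi/180 times the 6371 km mean Earth radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .gdd import FeasibilityMask
from .grids import EARTH_RADIUS_KM, CellAreaField, LatLonGrid, RegionMask

KM_PER_DEGREE_LAT = np.pi * EARTH_RADIUS_KM / 180.0  # ~111.195


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero upward)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ZonalSummary:
    region: str
    period: str
    total_region_area: float  # 1e6 km^2
    feasible_area: float  # 1e6 km^2
    feasible_pct: float  # 100 * feasible / total
    model_range: tuple[float, float] | None = None  # (min %, max %)

    @classmethod
    def from_areas(
        cls, region: str, period: str, total_area: float, feasible_area: float,
        model_range: tuple[float, float] | None = None,
    ) -> "ZonalSummary":
        """Build directly from areas (1e6 km^2), e.g. printed-table entries."""
        if not 0 <= feasible_area <= total_area:
            raise ValueError("feasible area must lie in [0, total area]")
        return cls(region, period, total_area, feasible_area,
                   100.0 * feasible_area / total_area, model_range)


@dataclass
class GainSummary:
    region: str
    baseline_period: str
    final_period: str
    area_gain: float  # 1e6 km^2
    pct_increase: float | None  # None when baseline feasible area is 0


@dataclass
class ShiftProfile:
    longitudes: np.ndarray
    baseline_edge_lat: np.ndarray  # NaN where absent
    future_edge_lat: np.ndarray
    shift_km: np.ndarray  # NaN where either edge absent
    new_colonization: np.ndarray  # bool: future edge exists, baseline absent

    def max_shift_km(self) -> float:
        ok = ~np.isnan(self.shift_km)
        return float(np.max(self.shift_km[ok])) if ok.any() else float("nan")

    def sector_max_km(self, lon_min: float, lon_max: float) -> float:
        sel = (self.longitudes >= lon_min) & (self.longitudes < lon_max)
        vals = self.shift_km[sel]
        ok = ~np.isnan(vals)
        return float(np.max(vals[ok])) if ok.any() else float("nan")


@dataclass
class LatBandSummary:
    band: tuple[float, float]  # [lower, upper) degrees
    continent: str
    feasible_area_per_model: np.ndarray  # 1e6 km^2 per model
    change_vs_baseline: np.ndarray | None = None  # 1e6 km^2 per model

    @property
    def label(self) -> str:
        lo, hi = self.band
        return f"{lo:g}–{hi - 1:g}°N" if lo >= 0 else f"{lo:g}–{hi - 1:g}°"


def zonal_summary(
    mask: FeasibilityMask,
    region: RegionMask,
    areas: CellAreaField,
    period: str,
    model_range: tuple[float, float] | None = None,
) -> ZonalSummary:
    """Feasible and total areas (1e6 km^2) and feasible percentage over a region."""
    if mask.grid != region.grid or mask.grid != areas.grid:
        raise ValueError("mask, region, and areas must share a grid")
    if not region.member.any():
        raise ValueError(f"region '{region.name}' is empty")
    total = areas.area[region.member].sum() / 1e6
    feasible = areas.area[region.member & mask.feasible].sum() / 1e6
    return ZonalSummary(region.name, period, total, feasible, 100.0 * feasible / total, model_range)


def gain_summary(baseline: ZonalSummary, final: ZonalSummary) -> GainSummary:
    """Area gain (final - baseline feasible) and percentage increase over baseline."""
    if baseline.region != final.region:
        raise ValueError("gain_summary requires summaries for the same region")
    gain = final.feasible_area - baseline.feasible_area
    pct = (100.0 * gain / baseline.feasible_area) if baseline.feasible_area > 0 else None
    return GainSummary(baseline.region, baseline.period, final.period, gain, pct)


def latitude_bands(lat_min: float, lat_max: float, width: float = 5.0):
    """Half-open [l, l+width) bands covering [lat_min, lat_max)."""
    lo = np.floor(lat_min / width) * width
    starts = np.arange(lo, lat_max, width)
    return [(float(s), float(s + width)) for s in starts]


def latitude_band_summary(
    masks: list[FeasibilityMask],
    bands: list[tuple[float, float]],
    continents: list[RegionMask],
    areas: CellAreaField,
    baseline_masks: list[FeasibilityMask] | None = None,
) -> list[LatBandSummary]:
    """Per (band, continent): feasible area per model, optionally the change
    against a per-model baseline. Continent masks must be pairwise disjoint."""
    grid = areas.grid
    for c in continents:
        if c.grid != grid:
            raise ValueError("continent masks must share the area grid")
    for i, a in enumerate(continents):
        for b in continents[i + 1 :]:
            if (a.member & b.member).any():
                raise ValueError(f"continent masks '{a.name}' and '{b.name}' overlap")
    if baseline_masks is not None and len(baseline_masks) != len(masks):
        raise ValueError("one baseline mask per model required")
    lat = grid.lat
    out = []
    for lo, hi in bands:
        in_band = (lat >= lo) & (lat < hi)
        for cont in continents:
            sel = cont.member & in_band[:, None]
            per_model = np.array(
                [areas.area[sel & m.feasible].sum() / 1e6 for m in masks]
            )
            change = None
            if baseline_masks is not None:
                base = np.array(
                    [areas.area[sel & m.feasible].sum() / 1e6 for m in baseline_masks]
                )
                change = per_model - base
            out.append(LatBandSummary((lo, hi), cont.name, per_model, change))
    return out


def leading_edge(mask: FeasibilityMask, min_contiguous: int = 1) -> np.ndarray:
    """Per-longitude leading-edge latitude (degrees), NaN where no edge.

    The edge is the maximum latitude whose cell is feasible and belongs to a
    run of at least ``min_contiguous`` consecutive feasible cells along its
    longitude column; isolated specks shorter than the run requirement are
    skipped.
    """
    if min_contiguous < 1:
        raise ValueError("min_contiguous must be >= 1")
    lat = mask.grid.lat
    nlat, nlon = mask.feasible.shape
    edge = np.full(nlon, np.nan)
    for j in range(nlon):
        col = mask.feasible[:, j]
        run = 0
        best = np.nan
        for i in range(nlat):
            run = run + 1 if col[i] else 0
            if run >= min_contiguous:
                best = lat[i]
        edge[j] = best
    return edge


def edge_shift(
    baseline_edge: np.ndarray,
    future_edge: np.ndarray,
    longitudes: np.ndarray,
    earth_radius_km: float = EARTH_RADIUS_KM,
) -> ShiftProfile:
    """Meridional shift (km, positive northward) per longitude column."""
    baseline_edge = np.asarray(baseline_edge, dtype=float)
    future_edge = np.asarray(future_edge, dtype=float)
    longitudes = np.asarray(longitudes, dtype=float)
    if baseline_edge.shape != future_edge.shape or baseline_edge.shape != longitudes.shape:
        raise ValueError("edge profiles and longitude axis must share a shape")
    km_per_deg = np.pi * earth_radius_km / 180.0
    shift = (future_edge - baseline_edge) * km_per_deg  # NaN propagates
    new_col = np.isnan(baseline_edge) & ~np.isnan(future_edge)
    return ShiftProfile(longitudes, baseline_edge, future_edge, shift, new_col)
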
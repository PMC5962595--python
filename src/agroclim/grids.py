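"""Gridded monthly climate fields: data model, NetCDF/CSV I/O, cell areas, regridding.

Conventions
-----------
* Grids are regular lat-lon, cell-center registered. A cell spans
  ``[center - res/2, center + res/2)`` in longitude and the analogous closed
  interval in latitude (edges clipped to the poles).
* Longitudes are normalized to ``[-180, 180)`` and stored ascending;
  latitudes ascending.
* Missing data are NaN in float arrays; boolean ``missing`` views are
  derived, never stored separately.
* Earth is a sphere of radius 6371 km for all area and distance figures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

EARTH_RADIUS_KM = 6371.0

VALID_VARIABLES = ("temperature", "precipitation")
UNITS = {"temperature": "degC", "precipitation": "mm/month"}


def normalize_lon(lon):
    """Map longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def _check_uniform(axis: np.ndarray, name: str, resolution: float) -> None:
    if axis.size > 1:
        steps = np.diff(axis)
        if not np.allclose(steps, resolution, rtol=0, atol=1e-8):
            raise ValueError(
                f"non-uniform spacing on {name} axis: expected {resolution}, "
                f"found steps in [{steps.min():.6g}, {steps.max():.6g}]"
            )


@dataclass(frozen=True)
class LatLonGrid:
    """Regular lat-lon grid of cell centers.

    Parameters
    ----------
    lat : 1-D array of cell-center latitudes, strictly ascending, inside (-90, 90).
    lon : 1-D array of cell-center longitudes in [-180, 180), strictly ascending.
    resolution : grid spacing in degrees (both axes).
    """

    lat: np.ndarray
    lon: np.ndarray
    resolution: float = 0.5

    def __post_init__(self):
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        if lat.ndim != 1 or lon.ndim != 1 or lat.size == 0 or lon.size == 0:
            raise ValueError("lat and lon must be non-empty 1-D arrays")
        if np.any(np.diff(lat) <= 0):
            raise ValueError("lat axis must be strictly ascending")
        if np.any(np.diff(lon) <= 0):
            raise ValueError("lon axis must be strictly ascending")
        if np.any(np.abs(lat) >= 90):
            raise ValueError("lat centers must lie strictly inside (-90, 90)")
        half = self.resolution / 2
        if lat[0] - half < -90 - 1e-9 or lat[-1] + half > 90 + 1e-9:
            raise ValueError("latitude cell edges extend beyond the poles")
        if np.any(lon < -180) or np.any(lon >= 180):
            raise ValueError("lon centers must lie in [-180, 180)")
        _check_uniform(lat, "lat", self.resolution)
        _check_uniform(lon, "lon", self.resolution)

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    def lat_edges(self) -> np.ndarray:
        half = self.resolution / 2
        edges = np.concatenate([self.lat - half, [self.lat[-1] + half]])
        return np.clip(edges, -90.0, 90.0)

    def is_global_lon(self) -> bool:
        """True if the lon axis wraps the full circle at this resolution."""
        span = (self.lon[0] - self.lon[-1]) % 360.0
        return self.lon.size * self.resolution >= 360.0 - 1e-9 and np.isclose(
            span, self.resolution
        )

    @classmethod
    def global_grid(cls, resolution: float = 0.5) -> "LatLonGrid":
        half = resolution / 2
        lat = np.arange(-90 + half, 90, resolution)
        lon = np.arange(-180 + half, 180, resolution)
        return cls(lat, lon, resolution)

    @classmethod
    def from_bounds(
        cls,
        lat_min: float,
        lat_max: float,
        lon_min: float = -180.0,
        lon_max: float = 180.0,
        resolution: float = 0.5,
    ) -> "LatLonGrid":
        """Grid of all cells whose centers fall in the given half-open bounds."""
        half = resolution / 2
        g = cls.global_grid(resolution)
        lat = g.lat[(g.lat >= lat_min + half - 1e-9) & (g.lat <= lat_max - half + 1e-9)]
        lon = g.lon[(g.lon >= lon_min) & (g.lon < lon_max)]
        return cls(lat, lon, resolution)

    def __eq__(self, other):
        if not isinstance(other, LatLonGrid):
            return NotImplemented
        return (
            self.resolution == other.resolution
            and np.array_equal(self.lat, other.lat)
            and np.array_equal(self.lon, other.lon)
        )


@dataclass
class MonthlyClimateSeries:
    """One climate variable on a grid over a contiguous monthly time axis.

    ``values`` has shape (n_times, n_lat, n_lon); missing cells are NaN.
    """

    grid: LatLonGrid
    variable: str
    times: list[tuple[int, int]]  # (year, month), contiguous
    values: np.ndarray

    def __post_init__(self):
        if self.variable not in VALID_VARIABLES:
            raise ValueError(f"variable must be one of {VALID_VARIABLES}")
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.times), *self.grid.shape)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        self.times = [(int(y), int(m)) for y, m in self.times]
        for (y0, m0), (y1, m1) in zip(self.times, self.times[1:]):
            nxt = (y0, m0 + 1) if m0 < 12 else (y0 + 1, 1)
            if (y1, m1) != nxt:
                raise ValueError(f"times not contiguous at {(y0, m0)} -> {(y1, m1)}")
        if self.variable == "precipitation":
            vals = self.values[~np.isnan(self.values)]
            if vals.size and vals.min() < 0:
                raise ValueError("precipitation values must be >= 0")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def time_index(self, year: int, month: int) -> int:
        try:
            return self.times.index((year, month))
        except ValueError:
            raise KeyError(f"({year}, {month}) not in series") from None

    def subset_years(self, start_year: int, end_year: int) -> "MonthlyClimateSeries":
        keep = [i for i, (y, _) in enumerate(self.times) if start_year <= y <= end_year]
        if not keep:
            raise ValueError("no times in requested year range")
        return MonthlyClimateSeries(
            self.grid,
            self.variable,
            [self.times[i] for i in keep],
            self.values[keep],
        )


@dataclass
class RegionMask:
    """Named boolean membership mask on a grid."""

    name: str
    grid: LatLonGrid
    member: np.ndarray

    def __post_init__(self):
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")


@dataclass
class CellAreaField:
    grid: LatLonGrid
    area: np.ndarray  # km^2 per cell, shape (n_lat, n_lon)


def cell_areas(grid: LatLonGrid, earth_radius_km: float = EARTH_RADIUS_KM) -> CellAreaField:
    """Spherical cell areas: A = R^2 * dlon_rad * (sin(lat_top) - sin(lat_bottom))."""
    edges = np.radians(grid.lat_edges())
    dlon = np.radians(grid.resolution)
    band = earth_radius_km**2 * dlon * (np.sin(edges[1:]) - np.sin(edges[:-1]))
    area = np.repeat(band[:, None], grid.lon.size, axis=1)
    return CellAreaField(grid, area)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _times_to_codes(times: Sequence[tuple[int, int]]) -> np.ndarray:
    # encode as YYYYMM integers: human-readable and NetCDF3-safe
    return np.array([y * 100 + m for y, m in times], dtype=np.int32)


def _codes_to_times(codes) -> list[tuple[int, int]]:
    return [(int(c) // 100, int(c) % 100) for c in np.asarray(codes)]


def write_monthly_grid(series: MonthlyClimateSeries, path: str) -> None:
    """Write a series to NetCDF (CF-style lat/lon/time) or CSV long format.

    Format is selected by extension: ``.csv`` writes the documented long
    format ``year,month,lat,lon,value`` (missing cells omitted); anything
    else is NetCDF via the scipy (NetCDF3) backend.
    """
    if str(path).endswith(".csv"):
        nt, nla, nlo = series.values.shape
        yy = np.array([t[0] for t in series.times])
        mm = np.array([t[1] for t in series.times])
        tt, la, lo = np.meshgrid(np.arange(nt), series.grid.lat, series.grid.lon, indexing="ij")
        flat = series.values.ravel()
        ok = ~np.isnan(flat)
        df = pd.DataFrame(
            {
                "year": yy[tt.ravel()[ok]],
                "month": mm[tt.ravel()[ok]],
                "lat": la.ravel()[ok],
                "lon": lo.ravel()[ok],
                "value": flat[ok],
            }
        )
        df.to_csv(path, index=False)
        return
    ds = xr.Dataset(
        {series.variable: (("time", "lat", "lon"), series.values)},
        coords={
            "time": _times_to_codes(series.times),
            "lat": series.grid.lat,
            "lon": series.grid.lon,
        },
    )
    ds[series.variable].attrs["units"] = UNITS[series.variable]
    ds["time"].attrs["units"] = "YYYYMM"
    ds.attrs["resolution"] = series.grid.resolution
    ds.to_netcdf(path, engine="scipy")


def _infer_resolution(lat: np.ndarray, lon: np.ndarray) -> float:
    for axis, name in ((lat, "lat"), (lon, "lon")):
        if axis.size > 1:
            steps = np.diff(np.sort(axis))
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-8):
                raise ValueError(f"non-uniform grid spacing on {name} axis")
    if lat.size > 1:
        return float(np.diff(np.sort(lat))[0])
    if lon.size > 1:
        return float(np.diff(np.sort(lon))[0])
    return 0.5


def _reject_kelvin(values: np.ndarray, variable: str) -> None:
    vals = values[~np.isnan(values)]
    if variable == "temperature" and vals.size and vals.min() > 150:
        raise ValueError(
            "temperature values all exceed 150: input looks like Kelvin; "
            "convert to degrees Celsius explicitly before reading"
        )


def read_monthly_grid(path: str, variable: str) -> MonthlyClimateSeries:
    """Read a monthly series from NetCDF or the CSV long format.

    Axes are re-sorted ascending regardless of file order; absent
    (time, lat, lon) combinations in CSV input become missing (NaN).
    """
    if variable not in VALID_VARIABLES:
        raise ValueError(f"variable must be one of {VALID_VARIABLES}")
    if str(path).endswith(".csv"):
        df = pd.read_csv(path)
        lat = np.sort(df["lat"].unique())
        lon = np.sort(normalize_lon(df["lon"].unique()))
        res = _infer_resolution(lat, lon)
        grid = LatLonGrid(lat, lon, res)
        codes = np.sort((df["year"] * 100 + df["month"]).unique())
        times = _codes_to_times(codes)
        values = np.full((len(times), lat.size, lon.size), np.nan)
        ti = {c: i for i, c in enumerate(codes)}
        li = {v: i for i, v in enumerate(lat)}
        gi = {v: i for i, v in enumerate(lon)}
        for row in df.itertuples(index=False):
            values[
                ti[row.year * 100 + row.month],
                li[row.lat],
                gi[normalize_lon(row.lon).item()],
            ] = row.value
        _reject_kelvin(values, variable)
        return MonthlyClimateSeries(grid, variable, times, values)

    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    name = variable if variable in ds else next(iter(ds.data_vars))
    da = ds[name]
    lat = np.asarray(ds["lat"], dtype=float)
    lon = normalize_lon(np.asarray(ds["lon"], dtype=float))
    lat_order = np.argsort(lat)
    lon_order = np.argsort(lon)
    values = np.asarray(da.transpose("time", "lat", "lon"), dtype=float)
    values = values[:, lat_order][:, :, lon_order]
    res = _infer_resolution(lat[lat_order], lon[lon_order])
    grid = LatLonGrid(lat[lat_order], lon[lon_order], res)
    times = _codes_to_times(np.asarray(ds["time"]))
    _reject_kelvin(values, variable)
    return MonthlyClimateSeries(grid, variable, times, values)


def write_mask(mask: RegionMask, path: str) -> None:
    ds = xr.Dataset(
        {"member": (("lat", "lon"), mask.member.astype(np.int8))},
        coords={"lat": mask.grid.lat, "lon": mask.grid.lon},
    )
    ds.attrs["name"] = mask.name
    ds.attrs["resolution"] = mask.grid.resolution
    ds.to_netcdf(path, engine="scipy")


def read_mask(path: str) -> RegionMask:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    lat = np.asarray(ds["lat"], dtype=float)
    lon = normalize_lon(np.asarray(ds["lon"], dtype=float))
    member = np.asarray(ds["member"]).astype(bool)
    grid = LatLonGrid(lat, lon, _infer_resolution(lat, lon))
    name = ds.attrs.get("name", os.path.splitext(os.path.basename(path))[0])
    return RegionMask(str(name), grid, member)


# ---------------------------------------------------------------------------
# Regridding
# ---------------------------------------------------------------------------

def _regrid_array(
    values: np.ndarray, src: LatLonGrid, target: LatLonGrid, method: str
) -> np.ndarray:
    """Regrid one 2-D array; no extrapolation (outside source extent -> NaN)."""
    out = np.full(target.shape, np.nan)
    if method == "nearest":
        li = np.searchsorted(src.lat, target.lat)
        li = np.clip(li, 1, src.lat.size - 1) if src.lat.size > 1 else np.zeros_like(li)
        if src.lat.size > 1:
            li = li - (target.lat - src.lat[li - 1] < src.lat[li] - target.lat)
        gi = np.searchsorted(src.lon, target.lon)
        gi = np.clip(gi, 1, src.lon.size - 1) if src.lon.size > 1 else np.zeros_like(gi)
        if src.lon.size > 1:
            gi = gi - (target.lon - src.lon[gi - 1] < src.lon[gi] - target.lon)
        half = src.resolution / 2 + 1e-9
        ok_lat = np.abs(target.lat - src.lat[li]) <= half
        ok_lon = np.abs(target.lon - src.lon[gi]) <= half
        sel = values[np.ix_(li, gi)]
        inside = np.outer(ok_lat, ok_lon)
        out[inside] = sel[inside]
        return out

    # bilinear on cell centers, NaN outside the source center envelope
    tlat, tlon = target.lat, target.lon
    in_lat = (tlat >= src.lat[0] - 1e-12) & (tlat <= src.lat[-1] + 1e-12)
    in_lon = (tlon >= src.lon[0] - 1e-12) & (tlon <= src.lon[-1] + 1e-12)
    if not in_lat.any() or not in_lon.any():
        return out
    yl = np.clip(np.searchsorted(src.lat, tlat[in_lat]) - 1, 0, max(src.lat.size - 2, 0))
    xl = np.clip(np.searchsorted(src.lon, tlon[in_lon]) - 1, 0, max(src.lon.size - 2, 0))
    yh = np.minimum(yl + 1, src.lat.size - 1)
    xh = np.minimum(xl + 1, src.lon.size - 1)
    dy = src.lat[yh] - src.lat[yl]
    dx = src.lon[xh] - src.lon[xl]
    wy = np.where(dy > 0, (tlat[in_lat] - src.lat[yl]) / np.where(dy > 0, dy, 1), 0.0)
    wx = np.where(dx > 0, (tlon[in_lon] - src.lon[xl]) / np.where(dx > 0, dx, 1), 0.0)
    v00 = values[np.ix_(yl, xl)]
    v01 = values[np.ix_(yl, xh)]
    v10 = values[np.ix_(yh, xl)]
    v11 = values[np.ix_(yh, xh)]
    wy2 = wy[:, None]
    wx2 = wx[None, :]
    interp = (
        v00 * (1 - wy2) * (1 - wx2)
        + v01 * (1 - wy2) * wx2
        + v10 * wy2 * (1 - wx2)
        + v11 * wy2 * wx2
    )
    block = np.full((in_lat.sum(), in_lon.sum()), np.nan)
    block[:] = interp
    out[np.ix_(in_lat, in_lon)] = block
    return out


def regrid(obj, target: LatLonGrid, method: str = "bilinear"):
    """Regrid a MonthlyClimateSeries or RegionMask onto ``target``.

    Masks accept nearest only. Bilinear never extrapolates: target cells
    outside the source cell-center envelope come back missing.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError("method must be 'nearest' or 'bilinear'")
    if isinstance(obj, RegionMask):
        if method != "nearest":
            raise ValueError("boolean masks must be regridded with method='nearest'")
        arr = _regrid_array(obj.member.astype(float), obj.grid, target, "nearest")
        return RegionMask(obj.name, target, np.nan_to_num(arr, nan=0.0) >= 0.5)
    if isinstance(obj, MonthlyClimateSeries):
        new = np.stack(
            [_regrid_array(frame, obj.grid, target, method) for frame in obj.values]
        )
        if obj.variable == "precipitation":
            # bilinear can produce -1e-17 level noise at zero boundaries
            new = np.where(new < 0, np.maximum(new, 0.0), new)
        return MonthlyClimateSeries(target, obj.variable, list(obj.times), new)
    raise TypeError(f"cannot regrid object of type {type(obj).__name__}")
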
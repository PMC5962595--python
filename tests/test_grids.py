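import math

import numpy as np
import pytest

from agroclim import (
    EARTH_RADIUS_KM,
    LatLonGrid,
    MonthlyClimateSeries,
    RegionMask,
    cell_areas,
    read_mask,
    read_monthly_grid,
    regrid,
    write_mask,
    write_monthly_grid,
)


def make_series(grid, variable="temperature", n_months=3, fill=10.0):
    times = []
    y, m = 2000, 1
    for _ in range(n_months):
        times.append((y, m))
        y, m = (y, m + 1) if m < 12 else (y + 1, 1)
    values = np.full((n_months, *grid.shape), fill)
    return MonthlyClimateSeries(grid, variable, times, values)


class TestLatLonGrid:
    def test_rejects_nonuniform_lat(self):
        with pytest.raises(ValueError, match="lat"):
            LatLonGrid(np.array([0.0, 1.0, 2.5]), np.array([0.0, 1.0]), 1.0)

    def test_rejects_nonuniform_lon(self):
        with pytest.raises(ValueError, match="lon"):
            LatLonGrid(np.array([0.0, 1.0]), np.array([0.0, 1.0, 2.5]), 1.0)

    def test_rejects_lat_center_at_pole(self):
        with pytest.raises(ValueError):
            LatLonGrid(np.array([89.0, 90.0]), np.array([0.0]), 1.0)

    def test_rejects_descending(self):
        with pytest.raises(ValueError):
            LatLonGrid(np.array([2.0, 1.0]), np.array([0.0]), 1.0)

    def test_global_grid_wraps(self):
        g = LatLonGrid.global_grid(0.5)
        assert g.shape == (360, 720)
        assert g.is_global_lon()
        # spacing between last and first (mod 360) equals resolution
        assert math.isclose((g.lon[0] - g.lon[-1]) % 360.0, 0.5)

    def test_from_bounds_half_open_lon(self):
        g = LatLonGrid.from_bounds(50.0, 60.0, -10.0, 10.0, 0.5)
        assert g.lat[0] == 50.25 and g.lat[-1] == 59.75
        assert g.lon[0] == -9.75 and g.lon[-1] == 9.75


class TestCellAreas:
    def test_equator_cell_matches_closed_form(self):
        # oracle: direct evaluation of R^2 * dlam * (sin 0.25deg - sin(-0.25deg))
        g = LatLonGrid(np.array([0.0]), np.array([0.0]), 0.5)
        oracle = EARTH_RADIUS_KM**2 * math.radians(0.5) * (
            math.sin(math.radians(0.25)) - math.sin(math.radians(-0.25))
        )
        assert cell_areas(g).area[0, 0] == pytest.approx(oracle, rel=1e-12)
        assert oracle == pytest.approx(3091.07, abs=0.01)

    def test_global_sum_is_sphere_area(self):
        g = LatLonGrid.global_grid(0.5)
        total = cell_areas(g).area.sum()
        sphere = 4 * math.pi * EARTH_RADIUS_KM**2
        assert abs(total - sphere) / sphere < 1e-3

    def test_hemispheric_symmetry(self):
        a_n = cell_areas(LatLonGrid(np.array([60.0]), np.array([0.0]), 0.5)).area[0, 0]
        a_s = cell_areas(LatLonGrid(np.array([-60.0]), np.array([0.0]), 0.5)).area[0, 0]
        assert a_n == pytest.approx(a_s, rel=1e-12)

    def test_area_decreases_with_abs_latitude(self):
        g = LatLonGrid(np.arange(0.25, 90, 0.5), np.array([0.0]), 0.5)
        band = cell_areas(g).area[:, 0]
        assert np.all(np.diff(band) < 0)
        assert np.all(band > 0)

    def test_band_area_closed_form(self):
        # sum over 50..60N band equals 2*pi*R^2*(sin 60 - sin 50) for full lon circle
        g = LatLonGrid.from_bounds(50.0, 60.0, -180.0, 180.0, 0.5)
        total = cell_areas(g).area.sum()
        closed = (
            2 * math.pi * EARTH_RADIUS_KM**2
            * (math.sin(math.radians(60)) - math.sin(math.radians(50)))
        )
        assert abs(total - closed) / closed < 1e-3


class TestIO:
    def test_netcdf_round_trip(self, small_grid, tmp_path):
        series = make_series(small_grid, n_months=4)
        series.values[1, 2, 3] = np.nan
        p = tmp_path / "t.nc"
        write_monthly_grid(series, str(p))
        back = read_monthly_grid(str(p), "temperature")
        assert back.grid == series.grid
        assert back.times == series.times
        np.testing.assert_array_equal(np.isnan(back.values), np.isnan(series.values))
        np.testing.assert_allclose(
            back.values[~np.isnan(back.values)], series.values[~np.isnan(series.values)]
        )

    def test_csv_round_trip_and_missing_row(self, small_grid, tmp_path):
        series = make_series(small_grid, variable="precipitation", fill=42.0)
        series.values[0, 0, 0] = np.nan  # omitted from CSV -> read back missing
        p = tmp_path / "p.csv"
        write_monthly_grid(series, str(p))
        back = read_monthly_grid(str(p), "precipitation")
        assert back.grid == series.grid
        assert np.isnan(back.values[0, 0, 0])
        ok = ~np.isnan(series.values)
        np.testing.assert_allclose(back.values[ok], series.values[ok])

    def test_descending_lat_normalized(self, small_grid, tmp_path):
        import xarray as xr

        series = make_series(small_grid, n_months=2)
        series.values[0] = small_grid.lat[:, None]  # value == its own latitude
        p = tmp_path / "desc.nc"
        ds = xr.Dataset(
            {"temperature": (("time", "lat", "lon"), series.values[:, ::-1, :])},
            coords={
                "time": np.array([200001, 200002]),
                "lat": small_grid.lat[::-1],
                "lon": small_grid.lon,
            },
        )
        ds.to_netcdf(p, engine="scipy")
        back = read_monthly_grid(str(p), "temperature")
        assert np.all(np.diff(back.grid.lat) > 0)
        np.testing.assert_allclose(back.values[0], small_grid.lat[:, None] * np.ones_like(back.values[0]))

    def test_kelvin_rejected(self, small_grid, tmp_path):
        series = make_series(small_grid, fill=283.0)
        p = tmp_path / "k.nc"
        write_monthly_grid(series, str(p))
        with pytest.raises(ValueError, match="Kelvin"):
            read_monthly_grid(str(p), "temperature")

    def test_units_attributes(self, small_grid, tmp_path):
        import xarray as xr

        for var, units in (("temperature", "degC"), ("precipitation", "mm/month")):
            p = tmp_path / f"{var}.nc"
            write_monthly_grid(make_series(small_grid, variable=var), str(p))
            with xr.open_dataset(p, engine="scipy") as ds:
                assert ds[var].attrs["units"] == units

    def test_mask_round_trip(self, small_grid, tmp_path):
        member = np.zeros(small_grid.shape, dtype=bool)
        member[3:7, 2:5] = True
        mask = RegionMask("test_region", small_grid, member)
        p = tmp_path / "mask.nc"
        write_mask(mask, str(p))
        back = read_mask(str(p))
        assert back.name == "test_region"
        np.testing.assert_array_equal(back.member, member)

    def test_noncontiguous_times_rejected(self, small_grid):
        values = np.zeros((2, *small_grid.shape))
        with pytest.raises(ValueError, match="contiguous"):
            MonthlyClimateSeries(small_grid, "temperature", [(2000, 1), (2000, 3)], values)

    def test_negative_precip_rejected(self, small_grid):
        values = np.full((1, *small_grid.shape), -1.0)
        with pytest.raises(ValueError, match="precipitation"):
            MonthlyClimateSeries(small_grid, "precipitation", [(2000, 1)], values)


class TestRegrid:
    def test_identity_both_methods(self, small_grid):
        series = make_series(small_grid)
        series.values[:] = np.random.default_rng(0).normal(size=series.values.shape)
        for method in ("nearest", "bilinear"):
            out = regrid(series, small_grid, method)
            np.testing.assert_allclose(out.values, series.values, atol=1e-12)

    def test_constant_preserved_on_finer_grid(self, small_grid):
        series = make_series(small_grid, fill=7.5)
        fine = LatLonGrid(
            np.arange(small_grid.lat[0], small_grid.lat[-1] + 0.5, 1.0),
            np.arange(small_grid.lon[0], small_grid.lon[-1] + 0.5, 1.0),
            1.0,
        )
        out = regrid(series, fine, "bilinear")
        inside = ~np.isnan(out.values)
        assert inside.any()
        np.testing.assert_allclose(out.values[inside], 7.5)

    def test_bilinear_reproduces_affine_in_latitude(self, small_grid):
        series = make_series(small_grid, n_months=1)
        series.values[0] = 3.0 * small_grid.lat[:, None] - 2.0
        fine = LatLonGrid(
            np.arange(small_grid.lat[0], small_grid.lat[-1] + 0.25, 1.0),
            np.arange(small_grid.lon[0], small_grid.lon[-1] + 0.25, 1.0),
            1.0,
        )
        out = regrid(series, fine, "bilinear")
        expected = 3.0 * fine.lat[:, None] - 2.0
        ok = ~np.isnan(out.values[0])
        np.testing.assert_allclose(out.values[0][ok], np.broadcast_to(expected, out.values[0].shape)[ok], atol=1e-9)

    def test_no_extrapolation(self, small_grid):
        series = make_series(small_grid, n_months=1)
        wider = LatLonGrid(
            np.arange(small_grid.lat[0] - 10, small_grid.lat[-1] + 11, 2.0),
            small_grid.lon,
            2.0,
        )
        out = regrid(series, wider, "bilinear")
        outside = (wider.lat < small_grid.lat[0]) | (wider.lat > small_grid.lat[-1])
        assert np.isnan(out.values[0][outside]).all()

    def test_bilinear_rejected_for_mask(self, small_grid):
        mask = RegionMask("m", small_grid, np.ones(small_grid.shape, dtype=bool))
        with pytest.raises(ValueError, match="nearest"):
            regrid(mask, small_grid, "bilinear")

    def test_mask_nearest_round_trip(self, small_grid):
        member = np.zeros(small_grid.shape, dtype=bool)
        member[::2] = True
        mask = RegionMask("m", small_grid, member)
        out = regrid(mask, small_grid, "nearest")
        np.testing.assert_array_equal(out.member, member)

    def test_bilinear_bounded_by_local_extremes(self, small_grid):
        rng = np.random.default_rng(3)
        series = make_series(small_grid, n_months=1)
        series.values[0] = rng.uniform(0, 100, small_grid.shape)
        fine = LatLonGrid(
            np.arange(small_grid.lat[0], small_grid.lat[-1] + 0.25, 0.5),
            np.arange(small_grid.lon[0], small_grid.lon[-1] + 0.25, 0.5),
            0.5,
        )
        out = regrid(series, fine, "bilinear")
        ok = ~np.isnan(out.values[0])
        assert out.values[0][ok].min() >= series.values[0].min() - 1e-9
        assert out.values[0][ok].max() <= series.values[0].max() + 1e-9
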
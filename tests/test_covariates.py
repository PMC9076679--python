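"""Covariate sampling, ice binaries, front distances, standardization."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from shapely.geometry import LineString

import ctcrw
from ctcrw.covariates import Raster, evenly_spaced_days


def grid_raster(values, lons, lats, times=None, temporal="static"):
    if times is None:
        da = xr.DataArray(values, coords={"lat": lats, "lon": lons},
                          dims=("lat", "lon"))
    else:
        da = xr.DataArray(values, coords={"time": times, "lat": lats,
                                          "lon": lons},
                          dims=("time", "lat", "lon"))
    return Raster(da, temporal)


LONS = np.arange(-50.0, -29.5, 1.0)
LATS = np.arange(-60.0, -39.5, 1.0)


class TestSampleRaster:
    def test_constant_field(self):
        ras = grid_raster(np.full((len(LATS), len(LONS)), 7.0), LONS, LATS)
        assert ctcrw.sample_raster(ras, -40.3, -50.7) == 7.0

    def test_linear_plane_is_exact_mid_cell(self):
        LON, LAT = np.meshgrid(LONS, LATS)
        ras = grid_raster(2.0 + 0.5 * LON - 0.25 * LAT, LONS, LATS)
        lon, lat = -40.5, -49.5
        expected = 2.0 + 0.5 * lon - 0.25 * lat
        assert ctcrw.sample_raster(ras, lon, lat) == pytest.approx(
            expected, abs=1e-6)

    def test_masked_cell_is_missing(self):
        v = np.full((len(LATS), len(LONS)), 1.0)
        v[5, 5] = np.nan
        ras = grid_raster(v, LONS, LATS)
        assert np.isnan(ctcrw.sample_raster(ras, LONS[5], LATS[5]))

    def test_outside_extent_is_missing(self):
        ras = grid_raster(np.ones((len(LATS), len(LONS))), LONS, LATS)
        assert np.isnan(ctcrw.sample_raster(ras, 100.0, -50.0))

    def test_daily_layer_uses_nearest_not_after(self):
        times = pd.to_datetime(["2018-01-01", "2018-01-02", "2018-01-03"])
        vals = np.stack([np.full((len(LATS), len(LONS)), float(k))
                         for k in range(3)])
        ras = grid_raster(vals, LONS, LATS, times, "daily")
        assert ctcrw.sample_raster(ras, -40, -50, "2018-01-02T18:00") == 1.0
        assert np.isnan(ctcrw.sample_raster(ras, -40, -50, "2017-12-31"))

    def test_monthly_layer_matches_calendar_month(self):
        times = pd.to_datetime(["2018-01-15", "2018-02-15"])
        vals = np.stack([np.full((len(LATS), len(LONS)), 10.0),
                         np.full((len(LATS), len(LONS)), 20.0)])
        ras = grid_raster(vals, LONS, LATS, times, "monthly")
        assert ctcrw.sample_raster(ras, -40, -50, "2018-02-02") == 20.0
        assert np.isnan(ctcrw.sample_raster(ras, -40, -50, "2018-03-02"))


class TestForwardFill:
    @pytest.mark.parametrize("vals,expected", [
        ([2.0, np.nan, np.nan, 5.0], [2.0, 2.0, 2.0, 5.0]),
        ([np.nan, 3.0], [3.0, 3.0]),
        ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]),
    ])
    def test_fill_rules(self, vals, expected):
        out = ctcrw.forward_fill(pd.Series(vals))
        assert out.tolist() == expected

    def test_entirely_missing_raises_naming_animal(self):
        with pytest.raises(ValueError, match="CHL.*w9"):
            ctcrw.forward_fill(pd.Series([np.nan, np.nan]), "w9", "CHL")


class TestIceBinary:
    def _daily(self, frac_by_day, year=2018, month=8):
        ndays = pd.Timestamp(year=year, month=month, day=1).days_in_month
        times = pd.to_datetime([f"{year}-{month:02d}-{d:02d}"
                                for d in range(1, ndays + 1)])
        vals = np.stack([np.full((len(LATS), len(LONS)), frac_by_day(d))
                         for d in range(1, ndays + 1)])
        return grid_raster(vals, LONS, LATS, times, "daily")

    def test_sampled_days_are_1_4_7_dots(self):
        assert evenly_spaced_days(31) == [1, 5, 9, 13, 17, 21, 25, 29]
        assert evenly_spaced_days(30) == [1, 4, 7, 10, 13, 16, 19, 22, 25, 28]

    def test_ice_free_month_is_zero(self):
        ras = self._daily(lambda d: 0.0)
        out = ctcrw.build_ice_binary(ras, 2018, 8, [-40.0], [-55.0])
        assert out.tolist() == [0]

    def test_perennial_ice_is_one(self):
        ras = self._daily(lambda d: 0.7)
        out = ctcrw.build_ice_binary(ras, 2018, 8, [-40.0], [-55.0])
        assert out.tolist() == [1]

    def test_only_sampled_days_count(self):
        # August (31 days) samples days 1,5,9,...; ice only on day 5 -> 1,
        # ice only on day 6 -> 0
        ras5 = self._daily(lambda d: 1.0 if d == 5 else 0.0)
        ras6 = self._daily(lambda d: 1.0 if d == 6 else 0.0)
        assert ctcrw.build_ice_binary(ras5, 2018, 8, [-40], [-55]).tolist() == [1]
        assert ctcrw.build_ice_binary(ras6, 2018, 8, [-40], [-55]).tolist() == [0]

    def test_missing_month_raises(self):
        ras = self._daily(lambda d: 0.0)
        with pytest.raises(ValueError, match="2019-08"):
            ctcrw.build_ice_binary(ras, 2019, 8, [-40], [-55])

    def test_deterministic(self):
        ras = self._daily(lambda d: 0.5 if d % 2 else 0.0)
        a = ctcrw.build_ice_binary(ras, 2018, 8, [-40, -45], [-55, -50])
        b = ctcrw.build_ice_binary(ras, 2018, 8, [-40, -45], [-55, -50])
        assert (a == b).all()


class TestDistanceToFront:
    FRONT = LineString([(-50.0, -60.0), (-30.0, -60.0)])

    def test_vertex_distance_zero(self):
        d = ctcrw.distance_to_front([-50.0], [-60.0], self.FRONT)
        assert d[0] < 1.0

    def test_one_degree_meridian_arc(self):
        d = ctcrw.distance_to_front([-40.0], [-59.0], self.FRONT)
        assert d[0] / 1000 == pytest.approx(111.19, rel=0.002)

    def test_densification_convergence(self):
        d1 = ctcrw.distance_to_front([-41.3], [-58.2], self.FRONT, chord_km=1.0)
        d2 = ctcrw.distance_to_front([-41.3], [-58.2], self.FRONT, chord_km=0.5)
        assert abs(d1[0] - d2[0]) / d2[0] < 0.001

    def test_symmetric_under_reversal(self):
        rev = LineString(list(self.FRONT.coords)[::-1])
        a = ctcrw.distance_to_front([-37.0, -44.0], [-57.0, -62.0], self.FRONT)
        b = ctcrw.distance_to_front([-37.0, -44.0], [-57.0, -62.0], rev)
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestStandardize:
    def test_standardized_moments(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"SST": rng.normal(8, 3, 500),
                           "ICE08": rng.integers(0, 2, 500).astype(float)})
        spec, out = ctcrw.standardize(df, ["SST"], ["ICE08"])
        assert abs(out["SST"].mean()) < 1e-10
        assert out["SST"].std(ddof=0) == pytest.approx(1.0, abs=1e-10)
        assert set(out["ICE08"].unique()) <= {0.0, 1.0}

    def test_inverse_recovers_raw(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"SST": rng.normal(8, 3, 100)})
        spec, out = ctcrw.standardize(df, ["SST"])
        back = spec.inverse(out)
        np.testing.assert_allclose(back["SST"], df["SST"], rtol=1e-12)

    def test_pooled_spec_reused_on_subsets_commutes(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"id": ["a"] * 50 + ["b"] * 50,
                           "SST": rng.normal(8, 3, 100)})
        spec, out = ctcrw.standardize(df, ["SST"])
        sub = spec.transform(df[df["id"] == "a"])
        np.testing.assert_allclose(sub["SST"], out[out["id"] == "a"]["SST"])

    def test_field_spec_matches_generator_moments(self):
        cfg = ctcrw.SimConfig.recovery_default(seed=2)
        stack = ctcrw.gen_covariate_fields(cfg, 2)
        spec = ctcrw.field_standardization(stack)
        c, s = spec.params["SST"]
        fc = cfg.fields
        mid = fc.sst_ref + fc.sst_gradient * (
            (fc.lat_min + fc.lat_max) / 2 - fc.lat_ref)
        span_sd = fc.sst_gradient * (fc.lat_max - fc.lat_min) / np.sqrt(12)
        assert c == pytest.approx(mid, abs=1.0)
        assert s == pytest.approx(np.hypot(span_sd, fc.noise_sd), rel=0.05)

    def test_zero_variance_raises(self):
        df = pd.DataFrame({"SST": np.ones(10)})
        with pytest.raises(ValueError, match="SST"):
            ctcrw.standardize(df, ["SST"])


class TestCorrelationScreen:
    def test_independent_columns_not_forbidden(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"a": rng.normal(size=1000),
                           "b": rng.normal(size=1000)})
        assert ctcrw.correlation_screen(df, ["a", "b"]) == set()

    def test_copy_and_near_copy_forbidden(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=500)
        df = pd.DataFrame({"x": x, "x2": x, "y": x + rng.normal(0, 1e-3, 500)})
        out = ctcrw.correlation_screen(df, ["x", "x2", "y"])
        assert ("x", "x2") in out and ("x", "y") in out

    def test_generator_sst_chl_forbidden(self):
        cfg = ctcrw.SimConfig.recovery_default(seed=8)
        stack = ctcrw.gen_covariate_fields(cfg, 8)
        rng = np.random.default_rng(0)
        lons = rng.uniform(cfg.fields.lon_min, cfg.fields.lon_max, 10_000)
        lats = rng.uniform(cfg.fields.lat_min, cfg.fields.lat_max, 10_000)
        fixes = pd.DataFrame({"lon": lons, "lat": lats})
        table = ctcrw.sample_track(stack, fixes, ["SST", "CHL"])
        r = np.corrcoef(table["SST"], table["CHL"])[0, 1]
        assert abs(r) >= 0.5
        assert ("CHL", "SST") in ctcrw.correlation_screen(table, ["SST", "CHL"])
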
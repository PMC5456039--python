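import numpy as np
import pandas as pd
import pytest
import xarray as xr

from arstrack import RasterField, annotate, distance_to_front_km, match_time, \
    sample_bilinear
from arstrack.env import COVARIATES, FRONT_LAYER, TIME_WINDOWS_S


def grid(values, lon, lat, name="field"):
    return RasterField(name, xr.DataArray(np.asarray(values, float),
                                          coords={"lat": lat, "lon": lon},
                                          dims=("lat", "lon")))


class TestBilinear:
    def test_exact_at_grid_nodes(self):
        rng = np.random.default_rng(0)
        lon = np.linspace(-91, -88, 7)
        lat = np.linspace(21, 24, 5)
        vals = rng.normal(size=(5, 7))
        rf = grid(vals, lon, lat)
        for i in [0, 2, 4]:
            for j in [0, 3, 6]:
                assert sample_bilinear(rf, lon[j], lat[i])[0] == pytest.approx(
                    vals[i, j], abs=1e-12)

    def test_cell_centre_averages_four_corners(self):
        rf = grid([[1.0, 2.0], [3.0, 4.0]], [0.0, 1.0], [0.0, 1.0])
        assert sample_bilinear(rf, 0.5, 0.5)[0] == pytest.approx(2.5)

    def test_matches_two_pass_linear_oracle(self):
        rng = np.random.default_rng(5)
        lon = np.sort(rng.uniform(-91, -88, 9))
        lat = np.sort(rng.uniform(21, 24, 8))
        vals = rng.normal(size=(8, 9))
        rf = grid(vals, lon, lat)
        for _ in range(50):
            qlon = rng.uniform(lon[0], lon[-1])
            qlat = rng.uniform(lat[0], lat[-1])
            # independent: interpolate along lon within each lat row, then lat
            rows = np.array([np.interp(qlon, lon, vals[i]) for i in range(len(lat))])
            want = np.interp(qlat, lat, rows)
            assert sample_bilinear(rf, qlon, qlat)[0] == pytest.approx(want, abs=1e-12)

    def test_masked_neighbour_and_out_of_bounds_give_nan(self):
        vals = np.ones((3, 3))
        vals[1, 1] = np.nan
        rf = grid(vals, [0, 1, 2], [0, 1, 2])
        assert np.isnan(sample_bilinear(rf, 0.6, 0.6)[0])
        with pytest.warns(UserWarning):
            assert np.isnan(sample_bilinear(rf, 5.0, 1.0)[0])

    def test_continuity_across_cell_boundary(self):
        rng = np.random.default_rng(2)
        rf = grid(rng.normal(size=(4, 4)), np.arange(4.0), np.arange(4.0))
        eps = 1e-9
        a = sample_bilinear(rf, 1.0 - eps, 1.5)[0]
        b = sample_bilinear(rf, 1.0 + eps, 1.5)[0]
        assert a == pytest.approx(b, abs=1e-6)


class TestMatchTime:
    def _stack(self, times):
        da = xr.DataArray(
            np.arange(len(times) * 4, dtype=float).reshape(len(times), 2, 2),
            coords={"time": np.asarray(times, float), "lat": [0.0, 1.0],
                    "lon": [0.0, 1.0]},
            dims=("time", "lat", "lon"))
        return RasterField("wind_speed", da)

    def test_wind_query_at_0500_takes_0600_layer(self):
        hours = 3600.0
        rf = self._stack([0.0, 6 * hours, 12 * hours, 18 * hours])
        layer = match_time(rf, 5 * hours)
        assert float(layer.coords["time"]) == 6 * hours

    def test_exact_midpoint_takes_earlier_layer(self):
        rf = self._stack([0.0, 6 * 3600.0])
        layer = match_time(rf, 3 * 3600.0)
        assert float(layer.coords["time"]) == 0.0

    def test_beyond_window_is_missing(self):
        rf = self._stack([0.0])
        rf.name = "sst_daily"
        assert match_time(rf, 20 * 3600.0, window_s=TIME_WINDOWS_S["sst_daily"]) is None

    def test_static_raster_passes_through(self):
        rf = grid(np.ones((2, 2)), [0, 1], [0, 1])
        assert match_time(rf, 1e9) is rf.data


class TestDistanceToFront:
    def test_inside_frontal_cell_is_zero(self):
        vals = np.zeros((3, 3))
        vals[1, 1] = 0.8
        rf = grid(vals, [-90, -89, -88], [21, 22, 23], FRONT_LAYER)
        assert distance_to_front_km(rf, -89.0, 22.0)[0] == 0.0
        assert distance_to_front_km(rf, -89.1, 22.1)[0] == 0.0  # same cell

    def test_one_degree_north_is_about_111_km(self):
        vals = np.zeros((3, 3))
        vals[2, 1] = 1.0  # frontal cell at lat 23
        rf = grid(vals, [-90, -89, -88], [21, 22, 23], FRONT_LAYER)
        d = distance_to_front_km(rf, -89.0, 22.0)[0]
        assert d == pytest.approx(111.2, abs=0.5)

    def test_no_frontal_cells_returns_missing(self):
        rf = grid(np.zeros((2, 2)), [0, 1], [0, 1], FRONT_LAYER)
        assert np.isnan(distance_to_front_km(rf, 0.5, 0.5)[0])

    def test_threshold_excludes_weak_fronts(self):
        vals = np.zeros((2, 2))
        vals[0, 0] = 0.2
        rf = grid(vals, [0, 1], [0, 1], FRONT_LAYER)
        assert np.isfinite(distance_to_front_km(rf, 1.0, 1.0, threshold=0.0)[0])
        assert np.isnan(distance_to_front_km(rf, 1.0, 1.0, threshold=0.5)[0])


class TestAnnotate:
    def test_eleven_covariate_columns(self, small_study):
        bird = list(small_study.tracks)[0]
        from arstrack.tracks import build_bird_days
        bds, _ = build_bird_days(small_study.tracks[bird],
                                 small_study.config.colony_lonlat)
        rasters = {k: v for k, v in small_study.rasters.items()
                   if k != "distance_to_front"}
        res = annotate(bds[0].locations, rasters)
        assert all(c in res.table.columns for c in COVARIATES)
        assert res.completeness.min() > 0.99
        # covariates respect their observed ranges
        from arstrack.env import VARIABLE_RANGES
        for var in COVARIATES:
            lo, hi = VARIABLE_RANGES[var]
            vals = res.table[var].dropna()
            assert vals.between(lo - 1e-9, hi + 1e-9).all(), var

    def test_missing_raster_leaves_column_nan(self):
        loc = pd.DataFrame({"lon": [0.5], "lat": [0.5], "t": [0.0]})
        rf = grid(np.ones((2, 2)), [0, 1], [0, 1], "ssha")
        res = annotate(loc, {"ssha": rf})
        assert res.table["ssha"].iloc[0] == 1.0
        assert np.isnan(res.table["bathymetry"].iloc[0])
        assert res.completeness["bathymetry"] == 0.0

    def test_order_independence(self):
        rng = np.random.default_rng(9)
        loc = pd.DataFrame({"lon": rng.uniform(0, 1, 20),
                            "lat": rng.uniform(0, 1, 20),
                            "t": np.arange(20.0)})
        rf = grid(rng.normal(size=(5, 5)), np.linspace(0, 1, 5),
                  np.linspace(0, 1, 5), "ssha")
        a = annotate(loc, {"ssha": rf}).table
        perm = rng.permutation(20)
        b = annotate(loc.iloc[perm].reset_index(drop=True), {"ssha": rf}).table
        assert np.allclose(a["ssha"].to_numpy()[perm], b["ssha"].to_numpy())

    def test_noiseless_driver_band_reproduced_at_patch_centre(self):
        from arstrack import SimConfig, simulate_env_fields, simulate_track
        cfg = SimConfig(seed=9, n_birds=1, noise_sd={"ssha": 0.0, "velocity": 0.0})
        _, truth = simulate_track(cfg, 0, 0)
        fields = simulate_env_fields(cfg, [truth])
        b = truth.bouts_at_rank(0)[0]
        clon, clat = cfg.projection.inverse(b.center_x, b.center_y)
        loc = pd.DataFrame({"lon": [clon], "lat": [clat], "t": [b.t_start]})
        res = annotate(loc, {k: v for k, v in fields.items()
                             if k != "distance_to_front"})
        for var, band in cfg.driver_vars.items():
            assert res.table[var].iloc[0] == pytest.approx(
                0.5 * (band[0] + band[1]), abs=1e-12)
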
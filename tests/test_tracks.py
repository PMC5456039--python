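import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from arstrack import (build_bird_days, filter_speed, interpolate_100m, project,
                      split_trips, trip_descriptors)
from arstrack.tracks import Trip, remove_night_rest_and_split_days

COLONY = (-89.7, 22.4)


def _track_from_xy(x, y, t, colony=COLONY):
    from arstrack.geo import LocalProjection
    lon, lat = LocalProjection(*colony).inverse(np.asarray(x, float), np.asarray(y, float))
    return project(pd.DataFrame({"t": np.asarray(t, float), "lon": lon, "lat": lat}),
                   colony)


class TestSpeedFilter:
    def test_implanted_teleport_spikes_removed_exactly(self):
        rng = np.random.default_rng(0)
        n = 120
        t = 50.0 * np.arange(n)
        x = np.cumsum(rng.normal(500, 20, n))  # ~36 km/h forward drift
        y = rng.normal(0, 30, n)
        spikes = [30, 60, 90]
        x[spikes] += 40000.0  # teleports far beyond 90 km/h
        fixes = _track_from_xy(x, y, t)
        out = filter_speed(fixes)
        assert len(fixes) - len(out) == len(spikes)
        # independent recount: every remaining inter-fix speed is legal
        sp = np.hypot(np.diff(out["x"]), np.diff(out["y"])) / np.diff(out["t"]) * 3.6
        assert np.all(sp <= 90.0)

    def test_constant_legal_speed_untouched(self):
        t = 100.0 * np.arange(30)
        x = (50.0 / 3.6) * t  # constant 50 km/h
        fixes = _track_from_xy(x, np.zeros_like(x), t)
        out = filter_speed(fixes)
        assert len(out) == len(fixes)

    def test_fix_implying_95_kmh_removed(self):
        t = np.array([0.0, 100.0, 200.0])
        x = np.array([0.0, 95 / 3.6 * 100.0, 95 / 3.6 * 100.0 + 500.0])
        out = filter_speed(_track_from_xy(x, np.zeros(3), t))
        assert len(out) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        t = 50.0 * np.arange(80)
        x = np.cumsum(rng.normal(600, 300, 80))
        fixes = _track_from_xy(x, np.zeros_like(x), t)
        once = filter_speed(fixes)
        twice = filter_speed(once)
        pd.testing.assert_frame_equal(once, twice)


class TestSplitTrips:
    def test_never_leaving_buffer_yields_no_trips(self):
        rng = np.random.default_rng(1)
        t = 60.0 * np.arange(50)
        fixes = _track_from_xy(rng.normal(0, 100, 50), rng.normal(0, 100, 50), t)
        assert split_trips(fixes, buffer_m=1000) == []

    def test_single_excursion_bracketed_by_colony_fixes(self):
        t = 60.0 * np.arange(40)
        d = np.concatenate([np.zeros(5), np.linspace(0, 20000, 15),
                            np.linspace(20000, 0, 15), np.zeros(5)])
        fixes = _track_from_xy(d, np.zeros_like(d), t)
        trips = split_trips(fixes, buffer_m=1000)
        assert len(trips) == 1
        f = trips[0].fixes
        assert f["colony_dist_m"].iloc[0] <= 1000
        assert f["colony_dist_m"].iloc[-1] <= 1000
        assert (f["colony_dist_m"] > 1000).any()

    def test_simulated_bird_trip_count_matches_truth(self, small_study):
        cfg = small_study.config
        for bird_id, track in small_study.tracks.items():
            fixes = filter_speed(project(track, cfg.colony_lonlat))
            trips = split_trips(fixes)
            expected = {t.trip_id for t in small_study.truth_for(bird_id)}
            assert len(trips) == len(expected), bird_id


class TestInterpolation:
    def test_straight_kilometre_gives_eleven_points(self):
        seg = pd.DataFrame({"x": [0.0, 1000.0], "y": [0.0, 0.0], "t": [0.0, 100.0]})
        out = interpolate_100m(seg)
        assert len(out) == 11
        assert np.allclose(out["x"], 100.0 * np.arange(11))
        assert np.allclose(np.diff(out["t"]), 10.0)

    def test_l_shaped_path_respects_corner(self):
        # 150 m east then 150 m north: points at arc lengths 0,100,200,300
        seg = pd.DataFrame({"x": [0.0, 150.0, 150.0], "y": [0.0, 0.0, 150.0],
                            "t": [0.0, 15.0, 30.0]})
        out = interpolate_100m(seg)
        assert np.allclose(out["s"], [0.0, 100.0, 200.0, 300.0])
        assert np.allclose(out[["x", "y"]].to_numpy(),
                           [[0, 0], [100, 0], [150, 50], [150, 150]])

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_polyline_geometry_conserved(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 30)
        x = np.cumsum(rng.normal(0, 300, n))
        y = np.cumsum(rng.normal(0, 300, n))
        t = np.cumsum(rng.uniform(10, 60, n))
        seg = pd.DataFrame({"x": x, "y": y, "t": t})
        total = np.hypot(np.diff(x), np.diff(y)).sum()
        if total < 200:
            return
        out = interpolate_100m(seg)
        # uniform 100-m spacing in arc length except the final (shorter) step
        arc = np.diff(out["s"])
        assert np.allclose(arc[:-1], 100.0, atol=1e-9)
        assert arc[-1] <= 100.0 + 1e-9
        assert np.isclose(out["s"].iloc[-1], total, rtol=1e-9)
        # chord steps never exceed the arc spacing
        steps = np.hypot(np.diff(out["x"]), np.diff(out["y"]))
        assert np.all(steps <= 100.0 + 1e-6)
        # every output point lies on the input polyline
        for px, py in out[["x", "y"]].to_numpy():
            d = _point_to_polyline(px, py, x, y)
            assert d < 1e-6
        # re-interpolation preserves the uniform-spacing property (corners
        # are re-chorded, so points may shift but spacing stays 100 m)
        again = interpolate_100m(out)
        arc2 = np.diff(again["s"])
        assert np.allclose(arc2[:-1], 100.0, atol=1e-9)
        assert len(again) <= len(out)

    def test_zero_length_path_rejected(self):
        seg = pd.DataFrame({"x": [5.0, 5.0], "y": [1.0, 1.0], "t": [0.0, 10.0]})
        with pytest.raises(ValueError):
            interpolate_100m(seg)


def _point_to_polyline(px, py, x, y):
    best = np.inf
    for i in range(len(x) - 1):
        vx, vy = x[i + 1] - x[i], y[i + 1] - y[i]
        L2 = vx * vx + vy * vy
        s = 0.0 if L2 == 0 else np.clip(((px - x[i]) * vx + (py - y[i]) * vy) / L2, 0, 1)
        best = min(best, np.hypot(px - (x[i] + s * vx), py - (y[i] + s * vy)))
    return best


class TestDescriptorsAndDays:
    def test_out_and_back_descriptors(self):
        # 50 km out, 50 km back at 25 km/h -> 4 h, 100 km, max 50 km
        v = 25000.0 / 3600.0
        t = np.arange(0, 4 * 3600.0 + 1, 100.0)
        d = np.where(t <= 2 * 3600.0, v * t, 2 * 50000.0 - v * t)
        fixes = _track_from_xy(d, np.zeros_like(d), t)
        desc = trip_descriptors(Trip("b", 0, fixes))
        assert desc.duration_h == pytest.approx(4.0, rel=1e-6)
        assert desc.total_distance_km == pytest.approx(100.0, rel=1e-3)
        assert desc.max_colony_distance_km == pytest.approx(50.0, rel=1e-3)

    def test_simulated_descriptors_match_truth_extent(self, small_study):
        cfg = small_study.config
        _, descs = build_bird_days(small_study.tracks["b000"], cfg.colony_lonlat)
        # patches sit at 35-100% of the drawn trip range, so the realised
        # maximum colony distance spans roughly [0.3 min, 1.2 max]
        for d in descs:
            assert cfg.trip_range_km[0] * 0.3 <= d.max_colony_distance_km \
                <= cfg.trip_range_km[1] * 1.2
            assert d.duration_h > 0
            assert d.total_distance_km >= 2 * d.max_colony_distance_km * 0.8

    def test_multi_day_trip_splits_into_days(self):
        from arstrack import SimConfig
        from arstrack.simulate import _simulate_trip
        cfg = SimConfig(seed=42, n_birds=1, trip_range_km=(20, 35))
        rng = np.random.default_rng(0)
        df, truths = _simulate_trip(rng, cfg, "b0", 0, n_days=2,
                                    t_depart=1368781200.0)
        assert len(truths) == 2
        fixes = filter_speed(project(df, cfg.colony_lonlat))
        (trip,) = split_trips(fixes)
        days = remove_night_rest_and_split_days(trip, cfg.colony_lonlat[0])
        assert len(days) == 2
        # partition: day fixes + removed rest fixes = trip fixes
        kept = sum(len(d) for d in days)
        assert kept < len(trip.fixes)

    def test_single_day_trip_one_bird_day(self, single_day):
        cfg, track, truth = single_day
        bds, descs = build_bird_days(track, cfg.colony_lonlat)
        assert len(bds) == 1
        assert bds[0].day_index == 0
        arc = np.diff(bds[0].locations["s"])
        assert np.allclose(arc[:-1], 100.0, atol=1e-9)
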
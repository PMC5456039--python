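import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from arstrack import (DayForest, bootstrap_population_importance, default_mtry,
                      fit_day_forest, partial_dependence, smooth_pd_across_days,
                      standardize_importance)
from arstrack.env import COVARIATES
from arstrack.habitat import PDCurve, important_variable_tally


def synth_day(n=300, seed=0, driver="ssha", informative=True):
    """A bird-day design: ARS iff the driver is negative (when informative)."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({v: rng.normal(size=n) for v in COVARIATES})
    if informative:
        y = (df[driver] < 0).astype(int)
    else:
        y = rng.integers(0, 2, n)
    df["ars"] = y
    df["bird_id"] = "b0"
    df["trip_id"] = 0
    df["day_index"] = 0
    return df


class TestStandardize:
    def test_examples(self):
        raw = np.array([2.0, 3.0, 5.0] + [0.0] * 8)
        out = standardize_importance(raw)
        assert np.allclose(out[:3], [20.0, 30.0, 50.0])
        assert out.sum() == pytest.approx(100.0, abs=1e-9)
        uniform = standardize_importance(np.ones(11))
        assert np.allclose(uniform, 100.0 / 11.0)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0.0, 1e6), min_size=2, max_size=11),
           st.floats(1e-6, 1e6))
    def test_scale_invariance(self, raw, c):
        raw = np.asarray(raw)
        if raw.sum() <= 0:
            return
        a = standardize_importance(raw)
        b = standardize_importance(c * raw)
        assert np.allclose(a, b, atol=1e-6)
        assert a.sum() == pytest.approx(100.0, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            standardize_importance(np.zeros(11))


class TestDayForest:
    def test_default_mtry_is_three_for_eleven_predictors(self):
        assert default_mtry(11) == 3
        day = synth_day()
        model, _ = fit_day_forest(day, n_trees=20, seed=0)
        assert model.mtry_ == 3

    def test_separable_day_recovers_driver(self):
        # sized like a real interpolated bird-day (~1000 locations)
        day = synth_day(n=1000, seed=1, driver="ssha")
        model, prof = fit_day_forest(day, n_trees=100, seed=0)
        assert model.sensitivity_ >= 0.95
        assert model.specificity_ >= 0.95
        top = prof.variables[int(np.argmax(prof.relative_importance))]
        assert top == "ssha"
        assert prof.relative_importance.sum() == pytest.approx(100.0, abs=1e-9)

    def test_deterministic_under_seed(self):
        day = synth_day(n=200, seed=2)
        m1, p1 = fit_day_forest(day, n_trees=30, seed=7)
        m2, p2 = fit_day_forest(day, n_trees=30, seed=7)
        assert np.allclose(p1.relative_importance, p2.relative_importance)
        assert m1.sensitivity_ == m2.sensitivity_

    def test_validation_rows_disjoint_from_training(self):
        day = synth_day(n=150, seed=3)
        model, _ = fit_day_forest(day, n_trees=10, seed=0)
        n = len(day)
        for samp in model.model_.estimators_samples_:
            held = np.setdiff1d(np.arange(n), samp)
            assert len(held) > 0
            assert len(np.intersect1d(held, samp)) == 0
            assert len(samp) == int(2 * n / 3)

    def test_single_class_day_rejected(self):
        day = synth_day(n=100, seed=4)
        day["ars"] = 1
        with pytest.raises(ValueError):
            fit_day_forest(day, n_trees=10, seed=0)


class TestBootstrap:
    def _profiles(self, rows):
        recs = []
        for (bird, trip, day), imp in rows:
            rec = {"bird_id": bird, "trip_id": trip, "day_index": day}
            rec.update(dict(zip(COVARIATES, imp)))
            recs.append(rec)
        return pd.DataFrame(recs)

    def test_one_day_per_trip_gives_zero_sd(self):
        rng = np.random.default_rng(0)
        rows = []
        for b in range(5):
            imp = standardize_importance(rng.random(11))
            rows.append(((f"b{b}", 0, 0), imp))
        profiles = self._profiles(rows)
        out = bootstrap_population_importance(profiles, n_iter=50, seed=1)
        assert np.allclose(out.sd, 0.0, atol=1e-12)
        assert np.allclose(out.mean, profiles[list(COVARIATES)].mean().to_numpy())

    def test_iteration_means_sum_to_hundred(self):
        rng = np.random.default_rng(1)
        rows = []
        for b in range(6):
            for d in range(rng.integers(1, 4)):
                rows.append(((f"b{b}", 0, d), standardize_importance(rng.random(11))))
        profiles = self._profiles(rows)
        out = bootstrap_population_importance(profiles, n_iter=100, seed=2)
        assert np.allclose(out.iteration_means.sum(axis=1), 100.0, atol=1e-9)
        assert out.mean.sum() == pytest.approx(100.0, abs=1e-9)

    def test_one_day_per_bird_mode_uses_bird_strata(self):
        rng = np.random.default_rng(2)
        rows = []
        for trip in range(3):  # one bird, three trips
            rows.append((("b0", trip, 0), standardize_importance(rng.random(11))))
        profiles = self._profiles(rows)
        per_trip = bootstrap_population_importance(profiles, n_iter=200, seed=3,
                                                   one_day_per="trip")
        per_bird = bootstrap_population_importance(profiles, n_iter=200, seed=3,
                                                   one_day_per="bird")
        # per-trip averages all three trips each draw (sd 0); per-bird samples
        assert np.allclose(per_trip.sd, 0.0, atol=1e-12)
        assert per_bird.sd.max() > 0.0

    def test_empty_profiles_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_population_importance(pd.DataFrame(), n_iter=10, seed=0)


class TestPartialDependence:
    def test_threshold_band_shows_elevated_probability(self):
        rng = np.random.default_rng(5)
        n = 400
        df = pd.DataFrame({v: rng.normal(size=n) for v in COVARIATES})
        inside = (df["velocity"] > -0.5) & (df["velocity"] < 0.5)
        df["ars"] = inside.astype(int)
        df["bird_id"], df["trip_id"], df["day_index"] = "b0", 0, 0
        model, _ = fit_day_forest(df, n_trees=100, seed=0)
        pd_curve = partial_dependence(model, df, "velocity", grid_size=30)
        inside_mask = (pd_curve.grid > -0.4) & (pd_curve.grid < 0.4)
        outside_mask = np.abs(pd_curve.grid) > 0.8
        assert pd_curve.probability[inside_mask].mean() > \
            pd_curve.probability[outside_mask].mean() + 0.3
        assert np.all((pd_curve.probability >= 0) & (pd_curve.probability <= 1))

    def test_ignored_variable_has_flat_pd(self):
        day = synth_day(n=400, seed=6, driver="ssha")
        model, prof = fit_day_forest(day, n_trees=100, seed=0)
        j = list(COVARIATES).index("wind_speed")
        assert prof.relative_importance[j] < 10.0
        curve = partial_dependence(model, day, "wind_speed", grid_size=30)
        assert curve.probability.max() - curve.probability.min() < 0.05

    def test_grid_spans_observed_range(self):
        day = synth_day(n=200, seed=7)
        model, _ = fit_day_forest(day, n_trees=20, seed=0)
        curve = partial_dependence(model, day, "ssha", grid_size=25)
        assert curve.grid.min() >= day["ssha"].min() - 1e-12
        assert curve.grid.max() <= day["ssha"].max() + 1e-12


class TestSmoothPD:
    def test_identical_curves_pass_through_with_zero_band(self):
        g = np.linspace(0, 1, 40)
        p = 0.3 + 0.2 * np.sin(2 * np.pi * g)
        curves = [PDCurve("v", g.copy(), p.copy()) for _ in range(5)]
        out = smooth_pd_across_days(curves)
        gi = np.interp(out.grid, g, p)
        assert np.allclose(out.mean, gi, atol=0.01)
        assert np.allclose(out.upper - out.lower, 0.0, atol=1e-9)

    def test_noisy_copies_recover_truth(self):
        rng = np.random.default_rng(8)
        g = np.linspace(0, 1, 50)
        truth = 0.5 + 0.3 * np.cos(2 * np.pi * g)
        curves = [PDCurve("v", g.copy(), truth + rng.normal(0, 0.05, len(g)))
                  for _ in range(30)]
        out = smooth_pd_across_days(curves)
        gi = np.interp(out.grid, g, truth)
        assert np.max(np.abs(out.mean - gi)) < 0.05
        assert np.all(out.upper >= out.mean - 1e-12)

    def test_single_curve_pass_through(self):
        g = np.linspace(0, 1, 20)
        c = PDCurve("v", g, np.full(20, 0.4))
        out = smooth_pd_across_days([c])
        assert np.allclose(out.mean, 0.4)
        assert out.n_curves == 1


def test_important_variable_tally():
    rng = np.random.default_rng(0)
    rows = []
    for d in range(20):
        imp = standardize_importance(rng.random(11) + np.where(
            np.arange(11) == 0, 3.0, 0.0))
        rec = {"bird_id": f"b{d}", "trip_id": 0, "day_index": 0}
        rec.update(dict(zip(COVARIATES, imp)))
        rows.append(rec)
    tally = important_variable_tally(pd.DataFrame(rows))
    assert tally.idxmax() == COVARIATES[0]
    assert (tally >= 0).all() and (tally <= 1).all()
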
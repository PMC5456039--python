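"""Per-bird-day tree ensembles linking environment to area-restricted search.

Each bird-day gets its own classifier of ARS vs non-ARS locations from the
11 environmental covariates: an ensemble of Gini-impurity decision trees,
each grown on an independent random two-thirds of the day's locations
(drawn WITHOUT replacement) and validated on its held-out third, with three
randomly drawn candidate predictors per split (floor(sqrt(11))).  Variable
importance is the mean decrease in node impurity summed per variable and
averaged over trees, standardized so the 11 variables sum to 100% per day.

Day-level importances are carried to the population level by a stratified
bootstrap — each iteration picks one day per trip per bird (or one day per
bird within a sampling period) and averages — and marginal effects are read
from partial-dependence curves pooled across days with a penalized-spline
smooth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .env import COVARIATES

DEFAULT_N_TREES = 1000
DEFAULT_TRAIN_FRAC = 2.0 / 3.0
DEFAULT_MIN_LEAF = 1  # grow to purity, as R randomForest does for classification
DEFAULT_N_BOOT = 1000


def default_mtry(n_features: int) -> int:
    """Predictors considered per split: floor(sqrt(p)) (3 for 11 predictors)."""
    return max(1, int(np.floor(np.sqrt(n_features))))


def standardize_importance(raw) -> np.ndarray:
    """Scale non-negative raw Gini importances to percentages summing to 100."""
    r = np.asarray(raw, dtype=float)
    if np.any(r < 0):
        raise ValueError("raw importances must be non-negative")
    s = r.sum()
    if s <= 0:
        raise ValueError("all-zero importances cannot be standardized")
    return 100.0 * r / s


class DayForest(ClassifierMixin, BaseEstimator):
    """Ensemble-of-trees ARS classifier for a single bird-day.

    sklearn-compatible estimator.  After ``fit``:

    - ``raw_importances_``: per-variable mean decrease in node impurity,
      averaged over trees (unnormalized);
    - ``importances_``: the same standardized to sum to 100;
    - ``sensitivity_``, ``specificity_``, ``accuracy_``: held-out validation
      rates averaged over trees (each tree is scored on the third of the
      locations it never saw).

    Parameters
    ----------
    n_trees : int
        Ensemble size (default 1000).
    mtry : int or None
        Candidate predictors per split; None means floor(sqrt(p)).
    train_frac : float
        Fraction of locations per tree, drawn without replacement (2/3).
    min_leaf : int
        Minimum locations per leaf; trees otherwise grow to purity.
    random_state : int or None
        Seeds subsampling and split randomness; fixed seed, identical forest.
    """

    def __init__(self, n_trees: int = DEFAULT_N_TREES, mtry: int | None = None,
                 train_frac: float = DEFAULT_TRAIN_FRAC,
                 min_leaf: int = DEFAULT_MIN_LEAF,
                 random_state: int | None = None):
        self.n_trees = n_trees
        self.mtry = mtry
        self.train_frac = train_frac
        self.min_leaf = min_leaf
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (locations x predictors)")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("bird-day has a single response class; exclude it")
        mtry = self.mtry if self.mtry is not None else default_mtry(X.shape[1])
        self.mtry_ = mtry
        tree = DecisionTreeClassifier(criterion="gini", max_features=mtry,
                                      min_samples_leaf=self.min_leaf)
        self.model_ = BaggingClassifier(estimator=tree,
                                        n_estimators=self.n_trees,
                                        max_samples=self.train_frac,
                                        bootstrap=False,
                                        random_state=self.random_state)
        self.model_.fit(X, y)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = X.shape[1]

        n = len(y)
        pos = self.classes_[-1]  # ARS coded as the larger class label
        raw = np.zeros(X.shape[1])
        sens, spec, acc = [], [], []
        for est, samp in zip(self.model_.estimators_, self.model_.estimators_samples_):
            raw += est.tree_.compute_feature_importances(normalize=False)
            held = np.setdiff1d(np.arange(n), samp, assume_unique=False)
            if held.size == 0:
                continue
            pred = est.predict(X[held])
            truth = y[held]
            tp = np.sum((truth == pos) & (pred == pos))
            tn = np.sum((truth != pos) & (pred != pos))
            p_n = np.sum(truth == pos)
            n_n = np.sum(truth != pos)
            if p_n:
                sens.append(tp / p_n)
            if n_n:
                spec.append(tn / n_n)
            acc.append(np.mean(pred == truth))
        raw /= self.n_trees
        self.raw_importances_ = raw
        self.importances_ = standardize_importance(raw)
        self.sensitivity_ = float(np.mean(sens)) if sens else float("nan")
        self.specificity_ = float(np.mean(spec)) if spec else float("nan")
        self.accuracy_ = float(np.mean(acc)) if acc else float("nan")
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))


@dataclass
class ImportanceProfile:
    """Standardized per-day variable importance plus validation rates."""

    bird_id: str
    trip_id: int
    day_index: int
    variables: list[str]
    relative_importance: np.ndarray  # percentages, sum 100
    sensitivity: float
    specificity: float
    accuracy: float

    def to_row(self) -> dict:
        row = {"bird_id": self.bird_id, "trip_id": self.trip_id,
               "day_index": self.day_index, "sensitivity": self.sensitivity,
               "specificity": self.specificity, "accuracy": self.accuracy}
        row.update(dict(zip(self.variables, self.relative_importance)))
        return row


def fit_day_forest(day_design: pd.DataFrame, variables=COVARIATES,
                   response: str = "ars", n_trees: int = DEFAULT_N_TREES,
                   mtry: int | None = None, train_frac: float = DEFAULT_TRAIN_FRAC,
                   min_leaf: int = DEFAULT_MIN_LEAF, seed: int | None = None,
                   ) -> tuple[DayForest, ImportanceProfile]:
    """Fit a :class:`DayForest` on one bird-day design table.

    ``day_design`` holds one row per location with the predictor columns,
    a binary ``ars`` response, and bird/trip/day identifiers.  Rows with
    missing predictors are dropped.
    """
    variables = list(variables)
    sub = day_design.dropna(subset=variables)
    X = sub[variables].to_numpy(dtype=float)
    y = sub[response].to_numpy().astype(int)
    model = DayForest(n_trees=n_trees, mtry=mtry, train_frac=train_frac,
                      min_leaf=min_leaf, random_state=seed).fit(X, y)
    prof = ImportanceProfile(
        bird_id=str(sub["bird_id"].iloc[0]) if "bird_id" in sub else "",
        trip_id=int(sub["trip_id"].iloc[0]) if "trip_id" in sub else 0,
        day_index=int(sub["day_index"].iloc[0]) if "day_index" in sub else 0,
        variables=variables,
        relative_importance=model.importances_,
        sensitivity=model.sensitivity_,
        specificity=model.specificity_,
        accuracy=model.accuracy_)
    return model, prof


@dataclass
class BootstrapSummary:
    """Population-level importance: mean of bootstrapped means and SD."""

    variables: list[str]
    mean: np.ndarray
    sd: np.ndarray
    n_iterations: int
    iteration_means: np.ndarray  # (n_iterations, n_variables)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"variable": self.variables, "mean": self.mean,
                             "sd": self.sd})


def bootstrap_population_importance(profiles: pd.DataFrame, variables=COVARIATES,
                                    n_iter: int = DEFAULT_N_BOOT,
                                    seed: int | None = None,
                                    one_day_per: str = "trip",
                                    ) -> BootstrapSummary:
    """Stratified bootstrap of day-level importances to the population level.

    Each iteration draws one bird-day per stratum with replacement across
    iterations — per trip per bird (``one_day_per='trip'``, the all-periods
    analysis) or per bird (``one_day_per='bird'``, the within-period
    analysis) — and averages the standardized importances over the draw.
    """
    variables = list(variables)
    if not len(profiles):
        raise ValueError("no importance profiles supplied")
    if one_day_per == "trip":
        strata = profiles.groupby(["bird_id", "trip_id"]).indices
    elif one_day_per == "bird":
        strata = profiles.groupby(["bird_id"]).indices
    else:
        raise ValueError("one_day_per must be 'trip' or 'bird'")
    mat = profiles[variables].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    pools = [np.asarray(ix) for ix in strata.values()]
    means = np.empty((n_iter, len(variables)))
    for it in range(n_iter):
        rows = [pool[rng.integers(len(pool))] for pool in pools]
        means[it] = mat[rows].mean(axis=0)
    return BootstrapSummary(variables=variables, mean=means.mean(axis=0),
                            sd=means.std(axis=0, ddof=1) if n_iter > 1 else np.zeros(len(variables)),
                            n_iterations=n_iter, iteration_means=means)


def important_variable_tally(profiles: pd.DataFrame, variables=COVARIATES,
                             q: float = 0.75) -> pd.Series:
    """Share of bird-days in which each variable's importance exceeds the
    ``q`` quantile of all day-level importances (a consistency tally)."""
    variables = list(variables)
    mat = profiles[variables].to_numpy(dtype=float)
    cut = np.quantile(mat.ravel(), q)
    return pd.Series((mat > cut).mean(axis=0), index=variables)


@dataclass
class PDCurve:
    """Partial dependence of the ARS probability on one variable, one day."""

    variable: str
    grid: np.ndarray
    probability: np.ndarray


def partial_dependence(model: DayForest, day_design: pd.DataFrame, variable: str,
                       variables=COVARIATES, grid_size: int = 50) -> PDCurve:
    """Mean predicted ARS probability with ``variable`` forced across its
    observed quantile grid (flat, with a warning path, for a constant
    predictor)."""
    variables = list(variables)
    sub = day_design.dropna(subset=variables)
    X = sub[variables].to_numpy(dtype=float)
    j = variables.index(variable)
    vals = X[:, j]
    grid = np.unique(np.quantile(vals, np.linspace(0, 1, grid_size)))
    probs = np.empty(len(grid))
    pos_col = int(np.nonzero(model.classes_ == model.classes_[-1])[0][0])
    for g, v in enumerate(grid):
        Xm = X.copy()
        Xm[:, j] = v
        probs[g] = model.predict_proba(Xm)[:, pos_col].mean()
    return PDCurve(variable=variable, grid=grid, probability=probs)


@dataclass
class SmoothedPD:
    variable: str
    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_curves: int


def smooth_pd_across_days(curves: list[PDCurve], n_grid: int = 100,
                          lam: float | None = None) -> SmoothedPD:
    """Aggregate per-day partial-dependence curves with a spline smooth.

    Curves are evaluated on a common grid spanning the union of their
    supports (each only within its own range), averaged pointwise with a
    normal-approximation 95% band across days, and the mean is smoothed
    with a penalized smoothing spline (GCV-chosen penalty unless ``lam``
    is given).  A single curve passes through unchanged.
    """
    if not curves:
        raise ValueError("no curves supplied")
    variable = curves[0].variable
    if len(curves) == 1:
        c = curves[0]
        return SmoothedPD(variable, c.grid, c.probability,
                          c.probability.copy(), c.probability.copy(), 1)
    lo = min(float(c.grid.min()) for c in curves)
    hi = max(float(c.grid.max()) for c in curves)
    grid = np.linspace(lo, hi, n_grid)
    vals = np.full((len(curves), n_grid), np.nan)
    for i, c in enumerate(curves):
        inside = (grid >= c.grid.min() - 1e-12) & (grid <= c.grid.max() + 1e-12)
        if c.grid.size == 1:
            vals[i, inside] = c.probability[0]
        else:
            vals[i, inside] = np.interp(grid[inside], c.grid, c.probability)
    n_eff = np.sum(np.isfinite(vals), axis=0)
    mean = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=1)
    se = np.where(n_eff > 0, sd / np.sqrt(np.maximum(n_eff, 1)), np.nan)
    ok = np.isfinite(mean) & (n_eff >= 1)
    if ok.sum() >= 4 and np.ptp(mean[ok]) > 1e-12:
        spline = make_smoothing_spline(grid[ok], mean[ok], lam=lam)
        smooth = np.where(ok, spline(grid), mean)
    else:
        smooth = mean
    return SmoothedPD(variable, grid, smooth,
                      smooth - 1.96 * se, smooth + 1.96 * se, len(curves))
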
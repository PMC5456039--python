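"""Group comparisons of foraging behaviour: NMDS, perMANOVA, dispersion, chi-squared.

Behaviour metrics (trip descriptors or small-scale ARS characteristics) are
z-scored, circular angles enter as sin/cos pairs, and Euclidean distances
between rows feed a nonmetric multidimensional scaling ordination plus two
permutation tests: perMANOVA for location (do group centroids differ?) and a
multivariate dispersion test, an extension of Levene's test (do groups differ
in spread around their centroid?).  Trip-type proportions are compared with
Pearson chi-squared tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2_contingency
from sklearn.manifold import MDS

DEFAULT_N_PERM = 10_000


# --------------------------------------------------------------------- table
def metric_table(df: pd.DataFrame, metrics: list[str],
                 angle_metrics: tuple[str, ...] = (),
                 standardize: bool = True) -> np.ndarray:
    """Numeric feature matrix for multivariate comparison.

    Listwise-deletes rows with missing cells, z-scores each column, and
    expands circular columns (degrees) into sin/cos pairs.  Returns the
    matrix aligned with ``df.dropna(subset=metrics)``; use
    :func:`distance_matrix` for the corresponding distances.
    """
    sub = df[metrics].dropna()
    cols = []
    for m in metrics:
        v = sub[m].to_numpy(dtype=float)
        if m in angle_metrics:
            rad = np.radians(v)
            cols.extend([np.sin(rad), np.cos(rad)])
        else:
            cols.append(v)
    X = np.column_stack(cols)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return X


def distance_matrix(X: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    return squareform(pdist(X, metric=metric))


# ---------------------------------------------------------------------- NMDS
def nmds(distances: np.ndarray, k: int = 2, n_starts: int = 8,
         seed: int | None = None):
    """Nonmetric MDS of a symmetric distance matrix.

    Runs one classical-scaling-initialised fit plus ``n_starts`` random
    starts and keeps the configuration with the lowest Kruskal stress-1.
    Returns ``(configuration, stress)`` with stress in [0, 1].
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distances must be a symmetric square matrix")
    best = None
    for init, n_init in (("classical_mds", 1), ("random", max(1, n_starts))):
        m = MDS(n_components=k, metric_mds=False, metric="precomputed",
                init=init, n_init=n_init, max_iter=500, eps=1e-9,
                random_state=seed, normalized_stress=True)
        conf = m.fit_transform(D)
        if best is None or m.stress_ < best[1]:
            best = (conf, float(m.stress_))
    return best


# ----------------------------------------------------------------- perMANOVA
@dataclass
class PermTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    method: str
    groups: list


def _group_indices(labels):
    labels = np.asarray(labels)
    groups = [g for g in pd.unique(labels)]
    idx = [np.nonzero(labels == g)[0] for g in groups]
    return groups, idx


def _pseudo_f(D2: np.ndarray, perm: np.ndarray, group_sizes: list[int]) -> float:
    """perMANOVA pseudo-F for a permuted ordering of the observations.

    ``perm`` maps group slots to observation indices; the first
    ``group_sizes[0]`` entries form group 1, etc.  SS_total and SS_within
    come from sums of squared distances (Anderson's distance-based
    decomposition).
    """
    n = D2.shape[0]
    sst = D2[np.triu_indices(n, k=1)].sum() / n
    ssw = 0.0
    pos = 0
    for sz in group_sizes:
        members = perm[pos:pos + sz]
        sub = D2[np.ix_(members, members)]
        ssw += sub[np.triu_indices(sz, k=1)].sum() / sz
        pos += sz
    ssa = sst - ssw
    a = len(group_sizes)
    return (ssa / (a - 1)) / (ssw / (n - a))


def permanova(distances: np.ndarray, labels, n_perm: int = DEFAULT_N_PERM,
              seed: int | None = None, exact: bool = False) -> PermTestResult:
    """Permutational MANOVA on a distance matrix.

    ``p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)`` under random label
    permutations; with ``exact=True`` all distinct assignments of
    observations to groups are enumerated instead and p is the exact
    proportion with ``F >= F_obs`` (the observed assignment included).
    """
    D = np.asarray(distances, dtype=float)
    groups, idx = _group_indices(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = [len(i) for i in idx]
    if min(sizes) < 2:
        raise ValueError("every group needs n >= 2")
    D2 = D ** 2
    order = np.concatenate(idx)
    f_obs = _pseudo_f(D2, order, sizes)
    n = D.shape[0]
    if exact:
        # enumerate every distinct assignment of observations to the labelled
        # groups (permuting within a group leaves F unchanged, so one
        # membership set per group suffices)
        from itertools import combinations

        def partitions(pool, szs):
            if len(szs) == 1:
                yield (tuple(pool),)
                return
            for g0 in combinations(pool, szs[0]):
                chosen = set(g0)
                remaining = [p for p in pool if p not in chosen]
                for tail in partitions(remaining, szs[1:]):
                    yield (g0,) + tail

        fs = []
        for part in partitions(list(range(n)), sizes):
            perm = np.concatenate([np.array(g, dtype=int) for g in part])
            fs.append(_pseudo_f(D2, perm, sizes))
        fs = np.asarray(fs)
        p = float(np.mean(fs >= f_obs - 1e-12))
        return PermTestResult(f_obs, p, len(fs), "permanova-exact", groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _pseudo_f(D2, perm, sizes) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermTestResult(f_obs, p, n_perm, "permanova", groups)


# ------------------------------------------------------------ beta dispersion
def _pcoa_coords(D: np.ndarray):
    """Principal-coordinate embedding, keeping real and imaginary axes.

    Returns (coords_pos, coords_neg): axes with positive and negative
    eigenvalues, scaled by sqrt(|eigenvalue|).  Squared distances in the
    embedding are d+^2 - d-^2 (Anderson's correction for non-Euclidean
    dissimilarities).
    """
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    w, V = np.linalg.eigh((G + G.T) / 2)
    tol = 1e-8 * max(1.0, np.abs(w).max())
    pos = w > tol
    neg = w < -tol
    return V[:, pos] * np.sqrt(w[pos]), V[:, neg] * np.sqrt(-w[neg])


def _dispersion_distances(D: np.ndarray, idx) -> np.ndarray:
    """Distance of each observation to its group centroid in PCoA space."""
    cp, cn = _pcoa_coords(D)
    z = np.empty(D.shape[0])
    for members in idx:
        mp = cp[members] - cp[members].mean(axis=0)
        mn = (cn[members] - cn[members].mean(axis=0)) if cn.size else np.zeros((len(members), 0))
        d2 = (mp ** 2).sum(axis=1) - (mn ** 2).sum(axis=1)
        z[members] = np.sqrt(np.maximum(d2, 0.0))
    return z


def _anova_f(z: np.ndarray, idx) -> float:
    n = len(z)
    a = len(idx)
    grand = z.mean()
    ssb = sum(len(m) * (z[m].mean() - grand) ** 2 for m in idx)
    ssw = sum(((z[m] - z[m].mean()) ** 2).sum() for m in idx)
    if ssw <= 0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / (a - 1)) / (ssw / (n - a))


def beta_dispersion(distances: np.ndarray, labels, n_perm: int = DEFAULT_N_PERM,
                    seed: int | None = None) -> PermTestResult:
    """Multivariate homogeneity-of-dispersion test (Levene-type, by permutation).

    Each observation's distance to its group centroid is computed in
    principal-coordinate space; the one-way ANOVA F on those distances is
    compared against F values obtained by permuting the model residuals
    (distance minus own-group mean) across observations.
    """
    D = np.asarray(distances, dtype=float)
    groups, idx = _group_indices(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if min(len(i) for i in idx) < 2:
        raise ValueError("every group needs n >= 2")
    z = _dispersion_distances(D, idx)
    f_obs = _anova_f(z, idx)
    means = np.empty_like(z)
    for m in idx:
        means[m] = z[m].mean()
    resid = z - means
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        zp = resid[rng.permutation(len(z))]
        if _anova_f(zp, idx) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermTestResult(f_obs, p, n_perm, "beta-dispersion", groups)


def pairwise_permanova(distances: np.ndarray, labels, n_perm: int = DEFAULT_N_PERM,
                       seed: int | None = None) -> pd.DataFrame:
    """Post-hoc pairwise perMANOVAs with Holm-adjusted p-values."""
    D = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    groups = list(pd.unique(labels))
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            mask = (labels == groups[i]) | (labels == groups[j])
            sub = D[np.ix_(mask, mask)]
            res = permanova(sub, labels[mask], n_perm=n_perm, seed=seed)
            rows.append({"group_a": groups[i], "group_b": groups[j],
                         "pseudo_F": res.statistic, "p_value": res.p_value})
    out = pd.DataFrame(rows)
    if len(out):
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, oi in enumerate(order):
            running = max(running, (m - rank) * out["p_value"].iloc[oi])
            adj[oi] = min(1.0, running)
        out["p_holm"] = adj
    return out


# --------------------------------------------------------------- chi-squared
def chisq_trip_type(table) -> tuple[float, int, float]:
    """Pearson chi-squared test on a periods x {single, multi} count table.

    Returns (statistic, dof, p).  Warns through scipy when expected counts
    are degenerate; no continuity correction (matches the classical Pearson
    statistic for any table shape).
    """
    tab = np.asarray(table, dtype=float)
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("margins must be positive")
    stat, p, dof, _ = chi2_contingency(tab, correction=False)
    return float(stat), int(dof), float(p)
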
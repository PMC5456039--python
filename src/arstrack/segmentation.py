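"""Penalized-contrast segmentation and ARS labelling.

To turn a per-location log(FPT) series into contiguous ARS / non-ARS
stretches, the series is partitioned into K homogeneous segments by
dynamic programming: for every K the changepoints minimise the
within-segment sum of squared deviations (the contrast J(K)), exactly.  K
itself is chosen by a penalized rule on the decrease of the contrast: the
contrast curve is scaled to [0, 1] over K = 1..Kmax, successive decreases
are multiplied by (Kmax - 1) (so a featureless series has decreases near
1/(Kmax-1) and scores near 1 on this scale), and the chosen K is the
largest one whose scaled decrease exceeds a threshold S (default 0.75),
bounded to [Kmin, Kmax] = [2, 20].

Segments whose mean log FPT exceeds the overall day mean are labelled ARS
(strictly greater, so an exactly homogeneous day has no ARS); runs of
adjacent ARS segments merge into ARS zones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import circular_mean_deg

KMIN_DEFAULT = 2
KMAX_DEFAULT = 20
LMIN_DEFAULT = 5
CONTRAST_THRESHOLD = 0.75


def _segment_cost_row(s1, s2, j):
    """Contrast of segments ending at j (inclusive) for all starts i<=j.

    cost(i, j) = sum_{i..j} v^2 - (sum_{i..j} v)^2 / (j-i+1).
    """
    i = np.arange(j + 1)
    n = j + 1 - i
    tot = s1[j + 1] - s1[i]
    return (s2[j + 1] - s2[i]) - tot * tot / n


class LavielleSegmenter:
    """Exact minimum-contrast segmentation with penalized choice of K.

    sklearn-style: ``fit`` on a 1-D series populates ``n_segments_``,
    ``changepoints_`` (indices starting each segment after the first),
    ``labels_`` (segment id per point) and ``contrasts_`` (J(K) for
    K = 1..Kmax).

    Parameters
    ----------
    k_min, k_max : int
        Bounds on the number of segments (defaults 2 and 20).
    l_min : int
        Minimum segment length in points (default 5).
    threshold : float
        S in the penalized decrease rule (default 0.75).
    """

    def __init__(self, k_min: int = KMIN_DEFAULT, k_max: int = KMAX_DEFAULT,
                 l_min: int = LMIN_DEFAULT, threshold: float = CONTRAST_THRESHOLD):
        if k_min < 1 or k_max < k_min:
            raise ValueError("need 1 <= k_min <= k_max")
        self.k_min = k_min
        self.k_max = k_max
        self.l_min = l_min
        self.threshold = threshold

    def fit(self, series) -> "LavielleSegmenter":
        v = np.asarray(series, dtype=float)
        if v.ndim != 1:
            raise ValueError("series must be one-dimensional")
        n = len(v)
        self.n_points_ = n
        if n < 2 * self.l_min:
            # too short to place even two admissible segments
            self.fallback_ = True
            self.n_segments_ = 1
            self.changepoints_ = []
            self.labels_ = np.zeros(n, dtype=int)
            self.contrasts_ = None
            return self
        self.fallback_ = False
        k_max = min(self.k_max, n // self.l_min)
        k_min = min(self.k_min, k_max)

        s1 = np.concatenate([[0.0], np.cumsum(v)])
        s2 = np.concatenate([[0.0], np.cumsum(v * v)])
        lmin = self.l_min

        # A[k, j] = minimal contrast of splitting v[0..j] into k+1 segments
        A = np.full((k_max, n), np.inf)
        back = np.zeros((k_max, n), dtype=int)
        for j in range(n):
            costs = _segment_cost_row(s1, s2, j)
            if j + 1 >= lmin:
                A[0, j] = costs[0]
            for k in range(1, k_max):
                if j + 1 < (k + 1) * lmin:
                    break
                # last segment starts at i: needs i >= k*lmin, j-i+1 >= lmin
                i_lo = k * lmin
                i_hi = j - lmin + 1
                cand = A[k - 1, i_lo - 1:i_hi] + costs[i_lo:i_hi + 1]
                m = int(np.argmin(cand))
                A[k, j] = cand[m]
                back[k, j] = i_lo + m
        J = A[:, n - 1].copy()          # J[k-1] = contrast with k segments
        self.contrasts_ = J

        K = self._choose_k(J, k_min, k_max)
        self.n_segments_ = K
        # backtrack
        cps = []
        j = n - 1
        for k in range(K - 1, 0, -1):
            i = int(back[k, j])
            cps.append(i)
            j = i - 1
        self.changepoints_ = sorted(cps)
        labels = np.zeros(n, dtype=int)
        for seg_id, start in enumerate(self.changepoints_, start=1):
            labels[start:] = seg_id
        self.labels_ = labels
        return self

    def _choose_k(self, J: np.ndarray, k_min: int, k_max: int) -> int:
        if k_max == 1:
            return 1
        rng = J[0] - J[-1]
        if rng <= max(1e-12, 1e-12 * abs(J[0])):
            return k_min
        Jn = (J - J[-1]) / rng          # scaled to [0, 1], decreasing
        dec = (Jn[:-1] - Jn[1:]) * (k_max - 1)
        above = np.nonzero(dec > self.threshold)[0]
        K = int(above[-1]) + 2 if above.size else k_min
        return int(np.clip(K, k_min, k_max))

    def segment_means(self, series) -> np.ndarray:
        v = np.asarray(series, dtype=float)
        return np.array([v[self.labels_ == k].mean()
                         for k in range(self.n_segments_)])


def lavielle_segment(series, k_min: int = KMIN_DEFAULT, k_max: int = KMAX_DEFAULT,
                     l_min: int = LMIN_DEFAULT,
                     threshold: float = CONTRAST_THRESHOLD) -> LavielleSegmenter:
    """Convenience wrapper returning a fitted :class:`LavielleSegmenter`."""
    return LavielleSegmenter(k_min, k_max, l_min, threshold).fit(series)


def classify_ars(series, segmenter: LavielleSegmenter) -> np.ndarray:
    """Boolean ARS label per location: segment mean log FPT strictly above
    the overall mean."""
    v = np.asarray(series, dtype=float)
    overall = v.mean()
    means = segmenter.segment_means(v)
    return means[segmenter.labels_] > overall


def ars_zones(labels: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of True labels as (start, end) inclusive index pairs."""
    lab = np.asarray(labels, dtype=bool).astype(int)
    edges = np.diff(np.concatenate([[0], lab, [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0] - 1
    return list(zip(starts.tolist(), ends.tolist()))


@dataclass
class ARSMetrics:
    """Summary of small-scale ARS for one bird-day."""

    bird_id: str
    trip_id: int
    day_index: int
    n_scales: int
    scale_m: float | None
    n_zones: int
    duration_h: float | None
    distance_km: float | None
    colony_distance_km: float | None
    colony_angle_deg: float | None

    def to_dict(self):
        return {
            "bird_id": self.bird_id, "trip_id": self.trip_id,
            "day_index": self.day_index, "n_scales": self.n_scales,
            "scale_m": self.scale_m, "n_zones": self.n_zones,
            "duration_h": self.duration_h, "distance_km": self.distance_km,
            "colony_distance_km": self.colony_distance_km,
            "colony_angle_deg": self.colony_angle_deg,
        }


def ars_metrics(bird_day, labels, n_scales: int = 0,
                scale_m: float | None = None) -> ARSMetrics:
    """Zone count, duration, distance and colony geometry of a day's ARS.

    ``bird_day`` is a :class:`~arstrack.tracks.BirdDay`; ``labels`` is the
    per-location boolean ARS vector at the day's smallest scale.  With no
    ARS the spatial metrics are None and ``n_zones`` is 0.
    """
    loc = bird_day.locations
    lab = np.asarray(labels, dtype=bool)
    zones = ars_zones(lab)
    if not zones:
        return ARSMetrics(bird_day.bird_id, bird_day.trip_id, bird_day.day_index,
                          n_scales, scale_m, 0, None, None, None, None)
    t = loc["t"].to_numpy(float)
    x = loc["x"].to_numpy(float)
    y = loc["y"].to_numpy(float)
    step = np.hypot(np.diff(x), np.diff(y))
    dur = sum(t[e] - t[s] for s, e in zones) / 3600.0
    dist = sum(step[s:e].sum() for s, e in zones) / 1000.0
    cdist = float(loc["colony_dist_m"].to_numpy(float)[lab].mean()) / 1000.0
    angle = circular_mean_deg(loc["colony_bearing_deg"].to_numpy(float)[lab])
    return ARSMetrics(bird_day.bird_id, bird_day.trip_id, bird_day.day_index,
                      n_scales, scale_m, len(zones), dur, dist, cdist, angle)


def metrics_frame(metrics: list[ARSMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.to_dict() for m in metrics])
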
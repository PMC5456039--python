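"""First-passage time and the spatial scales of area-restricted search.

First-passage time (FPT) at a location is the time the animal needs to cross
a circle of radius r centred there, travelling along the track both forward
and backward from the location.  Plotting the variance of log(FPT) across
locations against r reveals the characteristic scales at which movement is
concentrated: tortuous search inflates FPT far more than commuting at radii
comparable to the patch size, so var(log FPT) peaks near the scale of
area-restricted search.

Exit instants are found by exact segment-circle intersection with linear
time interpolation, so on a polyline track the FPT is exact (not quantised
to fix intervals).  Locations whose circle is never exited before the track
ends (in either direction) have undefined FPT at that radius and are
excluded from the variance curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

DEFAULT_RADIUS_STEP_M = 10.0
MAX_RADIUS_M = 35000.0
SMALL_SCALE_MAX_M = 8000.0
VARLOG_MIN_DEFINED_FRAC = 0.5
SMOOTH_WINDOW_BINS = 5
PROMINENCE_FRAC = 0.05
PROMINENCE_FLOOR = 0.01


def radius_grid(r_max: float, step: float = DEFAULT_RADIUS_STEP_M) -> np.ndarray:
    """Radii from ``step`` up to ``r_max`` inclusive, at ``step`` increments."""
    if r_max < step:
        raise ValueError("r_max smaller than the radius step")
    n = int(np.floor(r_max / step + 1e-9))
    return step * np.arange(1, n + 1)


def rmax_from_data(colony_dist_m, cap_m: float = MAX_RADIUS_M,
                   step: float = DEFAULT_RADIUS_STEP_M) -> float:
    """Largest candidate radius: half the mean colony distance, floored to a
    10-m multiple and capped at 35 km."""
    d = np.asarray(colony_dist_m, dtype=float)
    if d.size == 0:
        raise ValueError("no colony distances supplied")
    r = min(float(np.mean(d)) / 2.0, cap_m)
    r = np.floor(r / step) * step
    if r < step:
        raise ValueError("degenerate: locations are all at the colony")
    return float(r)


def _directional_fpt(x, y, t, radii):
    """Forward passage times for every location and radius.

    For location i the circle is first exited inside the first forward
    segment whose far endpoint lies beyond r (distance to a fixed centre is
    convex along a segment, so no earlier segment can cross).  The running
    maximum of the distances is nondecreasing, which turns the search for
    that segment into a binary search per radius.
    """
    n = len(x)
    nr = len(radii)
    out = np.full((n, nr), np.nan)
    for i in range(n - 1):
        dx = x[i + 1:] - x[i]
        dy = y[i + 1:] - y[i]
        dist = np.hypot(dx, dy)
        runmax = np.maximum.accumulate(dist)
        # first forward point beyond each radius
        k = np.searchsorted(runmax, radii, side="right")
        valid = k < len(dist)
        if not valid.any():
            continue
        kv = k[valid]
        j = i + 1 + kv          # absolute index of the first point outside
        # segment from j-1 (inside or on) to j (outside); solve |u + s v| = r
        ux = x[j - 1] - x[i]
        uy = y[j - 1] - y[i]
        vx = x[j] - x[j - 1]
        vy = y[j] - y[j - 1]
        r = radii[valid]
        a = vx * vx + vy * vy
        b = ux * vx + uy * vy
        c = ux * ux + uy * uy - r * r
        disc = np.maximum(b * b - a * c, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (-b + np.sqrt(disc)) / a
        s = np.clip(np.where(a > 0, s, 1.0), 0.0, 1.0)
        t_cross = t[j - 1] + s * (t[j] - t[j - 1])
        out[i, valid] = t_cross - t[i]
    return out


@dataclass
class FPTProfile:
    """FPT per location and radius, plus the variance-of-log curve."""

    radii_m: np.ndarray
    fpt_s: np.ndarray                      # (n locations, n radii); NaN undefined
    varlog: np.ndarray = field(init=False)
    defined_frac: np.ndarray = field(init=False)

    def __post_init__(self):
        with np.errstate(invalid="ignore"):
            logf = np.log(self.fpt_s)
        defined = np.isfinite(logf)
        self.defined_frac = defined.mean(axis=0) if len(self.fpt_s) else np.zeros(0)
        v = np.full(len(self.radii_m), np.nan)
        for jj in np.nonzero(self.defined_frac >= VARLOG_MIN_DEFINED_FRAC)[0]:
            col = logf[defined[:, jj], jj]
            if col.size > 1:
                v[jj] = np.var(col)
        self.varlog = v


class FirstPassageTime:
    """Transformer computing FPT profiles over a radius grid.

    Parameters
    ----------
    radii_m : array-like, optional
        Candidate radii.  When omitted, the grid runs from ``step`` to half
        the mean colony distance (capped at 35 km) in ``step`` increments.
    step : float
        Radius increment for the default grid (10 m unless coarsened).
    """

    def __init__(self, radii_m=None, step: float = DEFAULT_RADIUS_STEP_M):
        self.radii_m = None if radii_m is None else np.asarray(radii_m, dtype=float)
        self.step = float(step)
        if self.radii_m is not None and np.any(self.radii_m <= 0):
            raise ValueError("radii must be positive")

    def transform(self, locations) -> FPTProfile:
        """Compute the FPT profile of one interpolated bird-day.

        ``locations`` is a DataFrame with columns x, y, t (and
        colony_dist_m when the radius grid is data-driven).
        """
        x = locations["x"].to_numpy(dtype=float)
        y = locations["y"].to_numpy(dtype=float)
        t = locations["t"].to_numpy(dtype=float)
        if self.radii_m is not None:
            radii = self.radii_m
        else:
            r_max = rmax_from_data(locations["colony_dist_m"], step=self.step)
            radii = radius_grid(r_max, self.step)
        fwd = _directional_fpt(x, y, t, radii)
        bwd = _directional_fpt(x[::-1], y[::-1], -t[::-1], radii)[::-1]
        return FPTProfile(radii_m=radii, fpt_s=fwd + bwd)


def first_passage_time(locations, radius_m: float) -> np.ndarray:
    """FPT (s) of every location at a single radius; NaN where undefined."""
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    prof = FirstPassageTime(radii_m=[radius_m]).transform(locations)
    return prof.fpt_s[:, 0]


@dataclass
class ScaleSet:
    """Detected ARS scales of one bird-day (radii of var-log-FPT maxima)."""

    scales_m: list[float]

    @property
    def n_scales(self) -> int:
        return len(self.scales_m)

    @property
    def smallest_m(self) -> float | None:
        return self.scales_m[0] if self.scales_m else None

    @property
    def largest_m(self) -> float | None:
        return self.scales_m[-1] if self.scales_m else None

    def small_scale(self, max_m: float = SMALL_SCALE_MAX_M) -> float | None:
        """Smallest detected scale at or below ``max_m`` (None when only
        mesoscale search was found)."""
        fine = [s for s in self.scales_m if s <= max_m]
        return fine[0] if fine else None


def detect_scales(profile: FPTProfile,
                  smooth_bins: int = SMOOTH_WINDOW_BINS,
                  prominence_frac: float = PROMINENCE_FRAC) -> ScaleSet:
    """Local maxima of the lightly smoothed var(log FPT) curve.

    The curve is smoothed with a short moving average and peaks must exceed
    a prominence floor (a fraction of the curve's range, with a small
    absolute floor so a flat curve yields no scales).  Scales are returned
    in ascending radius order; an empty set is legitimate.
    """
    v = profile.varlog
    ok = np.isfinite(v)
    if ok.sum() < smooth_bins + 2:
        return ScaleSet(scales_m=[])
    r = profile.radii_m[ok]
    vv = v[ok]
    kernel = np.ones(smooth_bins) / smooth_bins
    sm = np.convolve(vv, kernel, mode="same")
    # moving average shrinks the ends; trim half-windows to avoid edge peaks
    h = smooth_bins // 2
    if h and len(sm) > 2 * h:
        sm = sm[h:-h]
        r = r[h:-h]
    rng = float(sm.max() - sm.min())
    prom = max(prominence_frac * rng, PROMINENCE_FLOOR)
    peaks, _ = find_peaks(sm, prominence=prom)
    return ScaleSet(scales_m=sorted(float(r[p]) for p in peaks))
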
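"""Raw GPS fixes to analysis-ready bird-days.

The processing chain mirrors standard central-place-forager telemetry
practice: project fixes to local planar metres, drop fixes implying
unrealistic flight speeds (> 90 km/h), split the record into foraging trips
at a colony buffer, strip overnight on-water rest bouts, cut multi-day trips
into bird-days, and linearly interpolate each bird-day to uniform 100-m
spacing along the path (the unit on which first-passage-time analysis runs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import LocalProjection, initial_bearing_deg

log = logging.getLogger(__name__)

MAX_SPEED_KMH = 90.0
DEFAULT_COLONY_BUFFER_M = 1000.0
DEFAULT_SPACING_M = 100.0
MIN_DAY_LOCATIONS = 50

# local-solar night window for the rest rule
NIGHT_START_H, NIGHT_END_H = 20.0, 5.0
REST_MAX_SPEED_KMH = 2.0
REST_MIN_DURATION_S = 3600.0


@dataclass
class Trip:
    """One foraging trip: fixes bracketed by the colony departure/return fixes."""

    bird_id: str
    trip_id: int
    fixes: pd.DataFrame  # columns t, lon, lat, x, y, speed_kmh, colony_dist_m


@dataclass
class BirdDay:
    """One at-sea day, interpolated to uniform spacing along the path."""

    bird_id: str
    trip_id: int
    day_index: int
    locations: pd.DataFrame  # columns t, x, y, lon, lat, colony_dist_m, colony_bearing_deg
    spacing_m: float = DEFAULT_SPACING_M
    n_raw_fixes: int = 0

    @property
    def key(self) -> tuple:
        return (self.bird_id, self.trip_id, self.day_index)


@dataclass
class TripDescriptors:
    bird_id: str
    trip_id: int
    n_days: int
    duration_h: float
    total_distance_km: float
    max_colony_distance_km: float


def project(fixes: pd.DataFrame, colony_lonlat: tuple[float, float]) -> pd.DataFrame:
    """Add planar ``x``/``y`` (m), ``speed_kmh`` and ``colony_dist_m`` columns.

    Timestamps must be strictly increasing.  The speed of the first fix is 0.
    """
    proj = LocalProjection(*colony_lonlat)
    out = fixes.copy().reset_index(drop=True)
    t = out["t"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing within a track")
    x, y = proj.forward(out["lon"].to_numpy(float), out["lat"].to_numpy(float))
    out["x"] = x
    out["y"] = y
    out["colony_dist_m"] = np.hypot(x, y)
    out["speed_kmh"] = _speeds_kmh(x, y, t)
    return out


def _speeds_kmh(x, y, t):
    sp = np.zeros(len(x))
    if len(x) > 1:
        d = np.hypot(np.diff(x), np.diff(y))
        sp[1:] = d / np.diff(t) * 3.6
    return sp


def filter_speed(fixes: pd.DataFrame, max_kmh: float = MAX_SPEED_KMH) -> pd.DataFrame:
    """Iteratively remove fixes implying speeds above ``max_kmh``.

    The later fix of the first violating pair is removed and speeds are
    recomputed, until no violation remains.  Raises if everything but the
    first fix would be removed.
    """
    if len(fixes) < 2:
        raise ValueError("need at least two fixes")
    out = fixes.reset_index(drop=True)
    x = out["x"].to_numpy(float).copy()
    y = out["y"].to_numpy(float).copy()
    t = out["t"].to_numpy(float).copy()
    keep = np.ones(len(out), dtype=bool)
    removed = 0
    while True:
        xi, yi, ti = x[keep], y[keep], t[keep]
        sp = _speeds_kmh(xi, yi, ti)
        bad = np.nonzero(sp > max_kmh)[0]
        if bad.size == 0:
            break
        # index into the kept subset -> absolute index
        abs_idx = np.nonzero(keep)[0][bad[0]]
        keep[abs_idx] = False
        removed += 1
        if keep.sum() < 2:
            raise ValueError("speed filter removed all fixes")
    if removed:
        log.info("speed filter removed %d fix(es)", removed)
    out = out.loc[keep].reset_index(drop=True)
    out["speed_kmh"] = _speeds_kmh(out["x"].to_numpy(float),
                                   out["y"].to_numpy(float),
                                   out["t"].to_numpy(float))
    return out


def split_trips(fixes: pd.DataFrame, buffer_m: float = DEFAULT_COLONY_BUFFER_M,
                bird_id: str | None = None) -> list[Trip]:
    """Cut a projected track into foraging trips at the colony buffer.

    A trip is a maximal run of fixes beyond ``buffer_m`` from the colony,
    extended by the fix immediately before departure and immediately after
    return when they exist.  A track that never leaves the buffer yields an
    empty list (colony attendance only).
    """
    df = fixes.reset_index(drop=True)
    if bird_id is None:
        bird_id = str(df["bird_id"].iloc[0]) if "bird_id" in df and len(df) else ""
    outside = (df["colony_dist_m"].to_numpy(float) > buffer_m).astype(int)
    if outside.sum() == 0:
        return []
    edges = np.diff(np.concatenate([[0], outside, [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0] - 1
    trips = []
    for k, (s, e) in enumerate(zip(starts, ends)):
        s_ext = max(s - 1, 0)
        e_ext = min(e + 1, len(df) - 1)
        trips.append(Trip(bird_id=bird_id, trip_id=k,
                          fixes=df.iloc[s_ext:e_ext + 1].reset_index(drop=True)))
    return trips


def _local_hour(t: np.ndarray, colony_lon: float) -> np.ndarray:
    return ((t + colony_lon / 15.0 * 3600.0) % 86400.0) / 3600.0


def _windowed_speed_kmh(df: pd.DataFrame, window: int = 4) -> np.ndarray:
    """Speed over a trailing ``window``-fix displacement (jitter-robust)."""
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    t = df["t"].to_numpy(float)
    n = len(x)
    w = min(window, n - 1)
    if w < 1:
        return np.zeros(n)
    sp = np.empty(n)
    d = np.hypot(x[w:] - x[:-w], y[w:] - y[:-w])
    dt = t[w:] - t[:-w]
    sp[w:] = d / dt * 3.6
    sp[:w] = sp[w]
    return sp


def remove_night_rest_and_split_days(trip: Trip, colony_lon: float,
                                     rest_max_kmh: float = REST_MAX_SPEED_KMH,
                                     rest_min_s: float = REST_MIN_DURATION_S,
                                     ) -> list[pd.DataFrame]:
    """Strip overnight on-water rest bouts and return one frame per bird-day.

    A rest bout is a maximal run of fixes during local night (solar
    20:00-05:00 at the colony longitude) whose speeds all stay below
    ``rest_max_kmh`` and which lasts at least ``rest_min_s``.  Speed is
    measured over a short multi-fix window rather than fix-to-fix: at
    10-100 s cadence the instantaneous speed of a drifting bird is dominated
    by GPS jitter, which the window averages out.  The at-sea segments
    separated by removed bouts are the bird-days.
    """
    df = trip.fixes.reset_index(drop=True)
    t = df["t"].to_numpy(float)
    hour = _local_hour(t, colony_lon)
    night = (hour >= NIGHT_START_H) | (hour < NIGHT_END_H)
    slow = _windowed_speed_kmh(df) < rest_max_kmh
    cand = night & slow
    rest = np.zeros(len(df), dtype=bool)
    edges = np.diff(np.concatenate([[0], cand.astype(int), [0]]))
    for s, e in zip(np.nonzero(edges == 1)[0], np.nonzero(edges == -1)[0] - 1):
        if t[e] - t[s] >= rest_min_s:
            rest[s:e + 1] = True
    keep = ~rest
    seg_id = np.cumsum(np.concatenate([[0], (np.diff(rest.astype(int)) != 0)]))
    days = []
    for sid in np.unique(seg_id[keep]):
        seg = df.loc[keep & (seg_id == sid)].reset_index(drop=True)
        if len(seg) >= 2:
            days.append(seg)
    if len(days) > 1:
        log.info("trip %s/%d: removed %d rest fix(es), %d bird-days",
                 trip.bird_id, trip.trip_id, int(rest.sum()), len(days))
    return days


def interpolate_100m(day_fixes: pd.DataFrame,
                     spacing_m: float = DEFAULT_SPACING_M) -> pd.DataFrame:
    """Resample a bird-day onto points every ``spacing_m`` along its path.

    Output points lie exactly on the original polyline at cumulative arc
    lengths 0, s, 2s, ...; the original end point is kept, so the last step
    may be shorter.  Timestamps are interpolated linearly within each
    original segment.
    """
    x = day_fixes["x"].to_numpy(float)
    y = day_fixes["y"].to_numpy(float)
    t = day_fixes["t"].to_numpy(float)
    if len(x) < 2:
        raise ValueError("need at least two fixes to interpolate")
    seg = np.hypot(np.diff(x), np.diff(y))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("zero-length path cannot be interpolated")
    # collapse duplicate vertices so cum is strictly increasing
    uniq = np.concatenate([[True], np.diff(cum) > 0])
    cu, xu, yu, tu = cum[uniq], x[uniq], y[uniq], t[uniq]
    s = np.arange(0.0, total, spacing_m)
    if total - s[-1] > 1e-9:
        s = np.append(s, total)
    else:
        s[-1] = total
    out = pd.DataFrame({
        "s": s,
        "x": np.interp(s, cu, xu),
        "y": np.interp(s, cu, yu),
        "t": np.interp(s, cu, tu),
    })
    return out


def trip_descriptors(trip: Trip, n_days: int | None = None) -> TripDescriptors:
    """Duration (h), path length (km) and maximum colony distance (km)."""
    df = trip.fixes
    t = df["t"].to_numpy(float)
    dur_h = (t[-1] - t[0]) / 3600.0
    dist_km = float(np.hypot(np.diff(df["x"].to_numpy(float)),
                             np.diff(df["y"].to_numpy(float))).sum()) / 1000.0
    max_km = float(df["colony_dist_m"].max()) / 1000.0
    return TripDescriptors(bird_id=trip.bird_id, trip_id=trip.trip_id,
                           n_days=n_days if n_days is not None else 1,
                           duration_h=dur_h, total_distance_km=dist_km,
                           max_colony_distance_km=max_km)


def build_bird_days(track: pd.DataFrame, colony_lonlat: tuple[float, float],
                    buffer_m: float = DEFAULT_COLONY_BUFFER_M,
                    max_kmh: float = MAX_SPEED_KMH,
                    spacing_m: float = DEFAULT_SPACING_M,
                    min_locations: int = MIN_DAY_LOCATIONS,
                    ) -> tuple[list[BirdDay], list[TripDescriptors]]:
    """Full chain: project, speed-filter, split trips, split days, interpolate.

    Bird-days with fewer than ``min_locations`` interpolated locations are
    dropped (logged).  Returns the retained bird-days plus per-trip
    descriptors.
    """
    proj = LocalProjection(*colony_lonlat)
    fixes = project(track, colony_lonlat)
    fixes = filter_speed(fixes, max_kmh=max_kmh)
    bird_days: list[BirdDay] = []
    descriptors: list[TripDescriptors] = []
    for trip in split_trips(fixes, buffer_m=buffer_m):
        day_frames = remove_night_rest_and_split_days(trip, colony_lonlat[0])
        descriptors.append(trip_descriptors(trip, n_days=len(day_frames)))
        for d, seg in enumerate(day_frames):
            try:
                interp = interpolate_100m(seg, spacing_m=spacing_m)
            except ValueError:
                log.info("dropping degenerate day %s/%d/%d", trip.bird_id, trip.trip_id, d)
                continue
            if len(interp) < min_locations:
                log.info("dropping short bird-day %s/%d/%d (%d locations)",
                         trip.bird_id, trip.trip_id, d, len(interp))
                continue
            lon, lat = proj.inverse(interp["x"].to_numpy(), interp["y"].to_numpy())
            interp["lon"] = lon
            interp["lat"] = lat
            interp["colony_dist_m"] = np.hypot(interp["x"], interp["y"])
            interp["colony_bearing_deg"] = initial_bearing_deg(
                colony_lonlat[0], colony_lonlat[1], lon, lat)
            bird_days.append(BirdDay(bird_id=trip.bird_id, trip_id=trip.trip_id,
                                     day_index=d, locations=interp,
                                     spacing_m=spacing_m, n_raw_fixes=len(seg)))
    return bird_days, descriptors
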
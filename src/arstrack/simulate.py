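"""Synthetic tracking studies with recorded ground truth.

The generator emulates a GPS-tracking study of a colonial, central-place
foraging seabird: many birds, each contributing one to nine foraging trips
of one to three days from a fixed colony, with fixes every 10-100 s. Each
at-sea day alternates commuting legs (fast, nearly straight flight) with
area-restricted-search (ARS) bouts -- tortuous movement confined to a patch
of known centre and radius.  Nested search scales are produced by embedding
small bouts inside a larger search region.  Multi-day trips rest (near-zero
drift) on the water overnight.

Alongside the tracks the generator writes eleven gridded environmental
fields.  Two designated "driver" variables (by default SSHA and
surface-current velocity) take values inside a prescribed band wherever ARS
patches sit and outside that band elsewhere, so the habitat model's ability
to recover the drivers can be scored against ground truth; the remaining
fields are smooth random surfaces uncorrelated with behaviour.  Every field
stays inside the observed range of its real-world counterpart.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from .env import FRONT_LAYER, GRIDDED_VARIABLES, VARIABLE_RANGES, RasterField
from .geo import LocalProjection

ALLOWED_FIX_INTERVALS_S = (10, 33, 50, 100)

#: UTC start of each sampling period
PERIOD_STARTS = {
    "may2013": "2013-05-17",
    "nov2013": "2013-11-01",
    "dec2014": "2014-12-04",
}
PERIOD_WEIGHTS = {"may2013": 37 / 135, "nov2013": 58 / 135, "dec2014": 40 / 135}


@dataclass
class SimConfig:
    """Parameters of a simulated tracking study.

    Defaults reproduce the study design being emulated: 135 birds, 1-9 trips
    per bird (truncated-geometric, mean ~2.2), trips of 1-3 days in the mix
    67/30/3%, fixes every 50 s, commuting at ~10 m/s, ARS bouts inside 1-km
    patches, GPS jitter of 10 m, and driver bands of SSHA < 0 m and velocity
    0.05-0.1 m/s.
    """

    seed: int = 0
    n_birds: int = 135
    trips_per_bird_range: tuple[int, int] = (1, 9)
    day_mix: tuple[float, float, float] = (0.67, 0.30, 0.03)  # P(1,2,3-day trip)
    fix_interval_s: int = 50
    travel_speed_mps: float = 10.0
    ars_speed_mps: float = 3.0
    ars_patch_radii_m: tuple[float, ...] = (1000.0,)
    ars_bouts_per_day: int = 2
    ars_bout_duration_s: tuple[float, float] = (1500.0, 3000.0)
    nested_sub_bouts: int = 2
    night_rest: bool = True
    colony_lonlat: tuple[float, float] = (-89.7, 22.4)
    domain_extent: tuple[float, float, float, float] = (-90.9, -88.5, 21.2, 23.6)
    trip_range_km: tuple[float, float] = (20.0, 80.0)
    gps_noise_m: float = 10.0
    driver_vars: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"ssha": (-0.1, 0.0), "velocity": (0.05, 0.1)})
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"ssha": 0.02, "velocity": 0.008})
    driver_resolution_deg: float = 0.005
    raster_resolution_deg: float = 0.02
    front_resolution_deg: float = 0.05

    def __post_init__(self):
        if self.fix_interval_s not in ALLOWED_FIX_INTERVALS_S:
            raise ValueError(f"fix_interval_s must be one of {ALLOWED_FIX_INTERVALS_S}")
        radii = tuple(sorted(float(r) for r in self.ars_patch_radii_m))
        if radii and not (200.0 <= radii[0] and radii[-1] <= 35000.0):
            raise ValueError("ARS patch radii must lie within [200, 35000] m")
        self.ars_patch_radii_m = radii
        for var, band in self.driver_vars.items():
            lo, hi = VARIABLE_RANGES[var]
            if not (lo <= band[0] < band[1] <= hi):
                raise ValueError(f"driver band {band} for {var!r} outside "
                                 f"its observed range [{lo}, {hi}]")

    @property
    def projection(self) -> LocalProjection:
        return LocalProjection(*self.colony_lonlat)

    def local_utc_offset_s(self) -> float:
        """Solar time offset at the colony longitude."""
        return self.colony_lonlat[0] / 15.0 * 3600.0


@dataclass
class Bout:
    """One recorded ARS bout (ground truth), indices relative to its day's fixes."""

    start_idx: int
    end_idx: int          # inclusive
    t_start: float        # epoch seconds
    t_end: float
    center_x: float
    center_y: float
    radius_m: float
    scale_rank: int       # 0 = smallest simulated scale

    def to_dict(self):
        return dataclasses.asdict(self)


@dataclass
class TruthRecord:
    """Ground truth for one bird-day of simulated movement."""

    bird_id: str
    trip_id: int
    day_index: int
    n_fixes: int
    t_first: float
    t_last: float
    bouts: list[Bout] = field(default_factory=list)

    def bouts_at_rank(self, rank: int = 0) -> list[Bout]:
        return [b for b in self.bouts if b.scale_rank == rank]

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["bouts"] = [b.to_dict() for b in self.bouts]
        return d


# --------------------------------------------------------------------------
# low-level track building
# --------------------------------------------------------------------------

class _TrackBuilder:
    """Accumulates planar fixes at a constant cadence."""

    def __init__(self, x0: float, y0: float, t0: float, dt: float):
        self.xs = [float(x0)]
        self.ys = [float(y0)]
        self.ts = [float(t0)]
        self.dt = float(dt)

    def __len__(self):
        return len(self.xs)

    @property
    def pos(self):
        return self.xs[-1], self.ys[-1]

    @property
    def t(self):
        return self.ts[-1]

    def step_to(self, x, y):
        self.xs.append(float(x))
        self.ys.append(float(y))
        self.ts.append(self.ts[-1] + self.dt)

    def hold(self, t_until: float):
        """Repeat the current position (zero speed) until ``t_until``."""
        while self.ts[-1] + self.dt <= t_until:
            self.step_to(*self.pos)


def _commute(tb: _TrackBuilder, rng, target, speed_mps, heading_sd_deg=3.0):
    """Fast, nearly straight flight towards ``target`` (re-aimed every fix)."""
    step = speed_mps * tb.dt
    while True:
        x, y = tb.pos
        d = np.hypot(target[0] - x, target[1] - y)
        if d <= step:
            tb.step_to(*target)
            return
        theta = np.arctan2(target[0] - x, target[1] - y)
        theta += np.radians(rng.normal(0.0, heading_sd_deg))
        tb.step_to(x + step * np.sin(theta), y + step * np.cos(theta))


def _ars_walk(tb: _TrackBuilder, rng, cfg: SimConfig, center, radius_m, duration_s):
    """Tortuous bout confined to a disc: CRW with a reflecting pull to centre.

    Headings wander freely (sd 55 deg) while well inside the patch and turn
    towards the centre near the edge, so virtually all bout displacement
    stays within ``radius_m`` of the centre.
    """
    step = min(cfg.ars_speed_mps * tb.dt, 0.25 * radius_m)
    n_steps = max(2, int(duration_s / tb.dt))
    x, y = tb.pos
    theta = rng.uniform(0.0, 2.0 * np.pi)
    for _ in range(n_steps):
        d = np.hypot(x - center[0], y - center[1])
        if d > 0.9 * radius_m:
            theta = np.arctan2(center[0] - x, center[1] - y) + np.radians(rng.normal(0, 20.0))
        else:
            theta += np.radians(rng.normal(0.0, 55.0))
        x, y = x + step * np.sin(theta), y + step * np.cos(theta)
        d = np.hypot(x - center[0], y - center[1])
        if d > radius_m:  # hard clamp; rarely reached
            x = center[0] + (x - center[0]) * 0.97 * radius_m / d
            y = center[1] + (y - center[1]) * 0.97 * radius_m / d
        tb.step_to(x, y)


def _nested_bout(tb: _TrackBuilder, rng, cfg: SimConfig, center, radii, bouts, rank_offset=0):
    """Recursively simulate a bout at the largest radius of ``radii``.

    ``radii`` is ascending; the largest defines a search region inside which
    ``cfg.nested_sub_bouts`` bouts at the next smaller radius are embedded,
    linked by slow transit.  Bout records are appended for every level.
    """
    r = radii[-1]
    start_idx = len(tb)
    t_start = tb.t
    if len(radii) == 1:
        _ars_walk(tb, rng, cfg, center, r, rng.uniform(*cfg.ars_bout_duration_s))
    else:
        r_sub = radii[-2]
        for _ in range(cfg.nested_sub_bouts):
            rho = (r - r_sub) * np.sqrt(rng.uniform(0.05, 1.0))
            phi = rng.uniform(0.0, 2.0 * np.pi)
            sub_center = (center[0] + rho * np.sin(phi), center[1] + rho * np.cos(phi))
            _commute(tb, rng, sub_center, 0.5 * cfg.travel_speed_mps, heading_sd_deg=8.0)
            _nested_bout(tb, rng, cfg, sub_center, radii[:-1], bouts, rank_offset)
    bouts.append(Bout(start_idx, len(tb) - 1, t_start, tb.t,
                      center[0], center[1], r,
                      scale_rank=rank_offset + len(radii) - 1))


def _night_drift(tb: _TrackBuilder, rng, t_until: float, speed_mps=0.08):
    """Near-zero-speed drift on the water (resting) until ``t_until``."""
    theta = rng.uniform(0.0, 2.0 * np.pi)
    while tb.t + tb.dt <= t_until:
        theta += np.radians(rng.normal(0.0, 25.0))
        x, y = tb.pos
        step = speed_mps * tb.dt
        tb.step_to(x + step * np.sin(theta), y + step * np.cos(theta))


# --------------------------------------------------------------------------
# day / trip assembly
# --------------------------------------------------------------------------

def _plan_patches(rng, cfg: SimConfig, direction_rad: float, range_m: float,
                  n_bouts: int):
    """Patch centres strung along the trip's outbound direction."""
    if n_bouts == 0:
        return []
    fracs = np.sort(rng.uniform(0.35, 1.0, size=n_bouts))
    centers = []
    for f in fracs:
        d = f * range_m
        lateral = rng.normal(0.0, 0.08 * range_m)
        cx = d * np.sin(direction_rad) - lateral * np.cos(direction_rad)
        cy = d * np.cos(direction_rad) + lateral * np.sin(direction_rad)
        centers.append((cx, cy))
    return centers


def _simulate_trip(rng, cfg: SimConfig, bird_id: str, trip_id: int, n_days: int,
                   t_depart: float):
    """One foraging trip (possibly multi-day). Returns (fix DataFrame, truths).

    The trip starts and ends at the colony; on multi-day trips the bird
    drifts on the water between local 19:45 and 05:00.
    """
    radii = cfg.ars_patch_radii_m
    range_m = rng.uniform(*cfg.trip_range_km) * 1000.0
    if radii and radii[-1] > 0.5 * range_m:
        raise ValueError(f"largest patch radius {radii[-1]:.0f} m exceeds half the "
                         f"trip extent {range_m:.0f} m; shrink the patches or "
                         f"extend trip_range_km")
    direction = rng.uniform(0.0, 2.0 * np.pi)
    offset = cfg.local_utc_offset_s()

    tb = _TrackBuilder(0.0, 0.0, t_depart, cfg.fix_interval_s)
    truths: list[TruthRecord] = []
    day_first_idx = 0

    for day in range(n_days):
        bouts: list[Bout] = []
        if day == 0:
            day_dir = direction + rng.normal(0, 0.15)
        else:
            # continue searching in the sector the bird woke up in, so the
            # morning commute never cuts back across the colony
            x0, y0 = tb.pos
            day_dir = np.arctan2(x0, y0) + rng.normal(0, 0.15)
        centers = _plan_patches(rng, cfg, day_dir, range_m, cfg.ars_bouts_per_day)
        for c in centers:
            approach = (c[0] - 1.2 * (radii[-1] if radii else 0.0) * np.sin(direction),
                        c[1] - 1.2 * (radii[-1] if radii else 0.0) * np.cos(direction))
            _commute(tb, rng, approach, cfg.travel_speed_mps)
            if radii:
                _nested_bout(tb, rng, cfg, c, radii, bouts)
        if not centers:
            # pure out-and-back commute
            far = (range_m * np.sin(direction), range_m * np.cos(direction))
            _commute(tb, rng, far, cfg.travel_speed_mps)

        last_day = day == n_days - 1
        if last_day:
            _commute(tb, rng, (0.0, 0.0), cfg.travel_speed_mps)
        else:
            # transit (commute-like: fast, nearly straight) until dusk, then
            # rest on the water overnight; headings fold back towards the
            # colony beyond the trip range so the bird stays inside the
            # study domain
            day_date = np.floor((tb.t + offset) / 86400.0)
            dusk = (day_date * 86400.0 + 19.75 * 3600.0) - offset
            theta = direction
            step = 0.7 * cfg.travel_speed_mps * tb.dt
            while tb.t + tb.dt <= dusk:
                x, y = tb.pos
                d = np.hypot(x, y)
                if d > 1.1 * range_m:
                    theta = np.arctan2(-x, -y) + np.radians(rng.normal(0.0, 10.0))
                elif d < 0.3 * range_m:  # keep clear of the colony buffer
                    theta = np.arctan2(x, y) + np.radians(rng.normal(0.0, 10.0))
                else:
                    theta += np.radians(rng.normal(0.0, 8.0))
                tb.step_to(x + step * np.sin(theta), y + step * np.cos(theta))
        day_last_idx = len(tb) - 1
        truths.append(TruthRecord(
            bird_id=bird_id, trip_id=trip_id, day_index=day,
            n_fixes=day_last_idx - day_first_idx + 1,
            t_first=tb.ts[day_first_idx], t_last=tb.ts[day_last_idx],
            bouts=[dataclasses.replace(
                b, start_idx=b.start_idx - day_first_idx,
                end_idx=b.end_idx - day_first_idx) for b in bouts]))
        if not last_day:
            if cfg.night_rest:
                day_date = np.floor((tb.t + offset) / 86400.0)
                dawn = ((day_date + 1) * 86400.0 + 5.0 * 3600.0) - offset
                _night_drift(tb, rng, dawn)
            day_first_idx = len(tb)

    x = np.asarray(tb.xs)
    y = np.asarray(tb.ys)
    if cfg.gps_noise_m > 0:
        x = x + rng.normal(0.0, cfg.gps_noise_m, size=x.shape)
        y = y + rng.normal(0.0, cfg.gps_noise_m, size=y.shape)
    lon, lat = cfg.projection.inverse(x, y)
    df = pd.DataFrame({
        "bird_id": bird_id,
        "trip_hint": trip_id,
        "t": np.asarray(tb.ts),
        "lon": lon,
        "lat": lat,
    })
    return df, truths


def simulate_track(config: SimConfig, bird_id: int | str = 0, day_index: int = 0):
    """Simulate one single-day foraging trip with ground truth.

    Seeded by ``(config.seed, bird_id, day_index)``: the same triple always
    yields byte-identical fixes.  Returns ``(track, truth)`` where ``track``
    has columns bird_id, trip_hint, t (epoch s), lon, lat and ``truth`` is a
    :class:`TruthRecord`.
    """
    idx = int(bird_id) if not isinstance(bird_id, str) else abs(hash(bird_id)) % (2**20)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1, idx, int(day_index))))
    name = bird_id if isinstance(bird_id, str) else f"b{idx:03d}"
    t0 = (pd.Timestamp(PERIOD_STARTS["may2013"], tz="UTC").timestamp()
          + day_index * 86400.0 + 12.5 * 3600.0 + rng.uniform(0, 7200))
    df, truths = _simulate_trip(rng, config, name, trip_id=0, n_days=1, t_depart=t0)
    return df, truths[0]


# --------------------------------------------------------------------------
# environmental fields
# --------------------------------------------------------------------------

def _grid_axes(extent, res):
    lon0, lon1, lat0, lat1 = extent
    lon = np.round(np.arange(lon0, lon1 + res / 2, res), 6)
    lat = np.round(np.arange(lat0, lat1 + res / 2, res), 6)
    return lon, lat


def _smooth_field(rng, shape, lo, hi, sigma=4.0):
    """Smoothed white noise rescaled to exactly span [lo, hi]."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    zmin, zmax = z.min(), z.max()
    if zmax - zmin < 1e-12:
        return np.full(shape, 0.5 * (lo + hi))
    return lo + (z - zmin) / (zmax - zmin) * (hi - lo)


def _outside_interval(var: str, band: tuple[float, float]):
    """Value interval used outside patches: inside the variable's range but
    clear of the driver band, on the side with more room."""
    lo, hi = VARIABLE_RANGES[var]
    margin = 0.1 * (hi - lo)
    room_above = hi - band[1]
    room_below = band[0] - lo
    if room_above >= room_below:
        return (min(band[1] + margin, hi - 1e-9), hi)
    return (lo, max(band[0] - margin, lo + 1e-9))


def simulate_env_fields(config: SimConfig,
                        truths: list[TruthRecord] | None = None,
                        patch_centers_xy: list[tuple[float, float, float]] | None = None,
                        ) -> dict[str, RasterField]:
    """Generate the 11 gridded fields (+ front layer) for a study.

    Driver variables equal their band midpoint (plus optional noise) inside
    every smallest-scale ARS patch footprint and sit outside the band
    elsewhere; other variables are smooth random surfaces.  Patch footprints
    come from ``truths`` (smallest-scale bouts) or, alternatively, from
    explicit ``patch_centers_xy`` triples ``(x, y, radius_m)``.
    """
    if patch_centers_xy is None:
        patch_centers_xy = []
        for tr in truths or []:
            for b in tr.bouts_at_rank(0):
                patch_centers_xy.append((b.center_x, b.center_y, b.radius_m))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    proj = config.projection
    fields: dict[str, RasterField] = {}

    for var in GRIDDED_VARIABLES:
        lo, hi = VARIABLE_RANGES[var]
        if var in config.driver_vars:
            band = config.driver_vars[var]
            res = config.driver_resolution_deg
            lon, lat = _grid_axes(config.domain_extent, res)
            out_lo, out_hi = _outside_interval(var, band)
            vals = _smooth_field(rng, (lat.size, lon.size), out_lo, out_hi, sigma=6.0)
            glon, glat = np.meshgrid(lon, lat)
            gx, gy = proj.forward(glon.ravel(), glat.ravel())
            gx = gx.reshape(glon.shape)
            gy = gy.reshape(glon.shape)
            mid = 0.5 * (band[0] + band[1])
            for (cx, cy, r) in patch_centers_xy:
                inside = (gx - cx) ** 2 + (gy - cy) ** 2 <= r ** 2
                vals[inside] = mid
            sd = config.noise_sd.get(var, 0.0)
            if sd > 0:
                vals = vals + rng.normal(0.0, sd, size=vals.shape)
            vals = np.clip(vals, lo, hi)
        else:
            res = config.raster_resolution_deg
            lon, lat = _grid_axes(config.domain_extent, res)
            vals = _smooth_field(rng, (lat.size, lon.size), lo, hi)
        fields[var] = RasterField(var, xr.DataArray(
            vals, coords={"lat": lat, "lon": lon}, dims=("lat", "lon")))

    # front probability: a wiggly zonal front near the colony
    res = config.front_resolution_deg
    lon, lat = _grid_axes(config.domain_extent, res)
    lat_front = config.colony_lonlat[1] + rng.uniform(-0.3, 0.3)
    wiggle = 0.15 * np.sin(2 * np.pi * (lon - lon[0]) / (lon[-1] - lon[0]) * 2
                           + rng.uniform(0, 2 * np.pi))
    prob = np.zeros((lat.size, lon.size))
    frontal = np.abs(lat[:, None] - (lat_front + wiggle[None, :])) <= res
    prob[frontal] = rng.uniform(0.5, 1.0, size=int(frontal.sum()))
    fields[FRONT_LAYER] = RasterField(FRONT_LAYER, xr.DataArray(
        prob, coords={"lat": lat, "lon": lon}, dims=("lat", "lon")))

    # convenience distance-to-front grid (km), capped at the observed maximum
    from .env import distance_to_front_km
    glon, glat = np.meshgrid(lon, lat)
    dtf = distance_to_front_km(fields[FRONT_LAYER], glon.ravel(), glat.ravel())
    dtf = np.minimum(dtf.reshape(glon.shape), VARIABLE_RANGES["distance_to_front"][1])
    fields["distance_to_front"] = RasterField("distance_to_front", xr.DataArray(
        dtf, coords={"lat": lat, "lon": lon}, dims=("lat", "lon")))
    return fields


# --------------------------------------------------------------------------
# whole-study assembly
# --------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """A complete simulated study: tracks, metadata, rasters, ground truth."""

    config: SimConfig
    metadata: pd.DataFrame
    tracks: dict[str, pd.DataFrame]
    rasters: dict[str, RasterField]
    truths: list[TruthRecord]

    def truth_for(self, bird_id: str, trip_id: int | None = None,
                  day_index: int | None = None) -> list[TruthRecord]:
        out = [t for t in self.truths if t.bird_id == bird_id]
        if trip_id is not None:
            out = [t for t in out if t.trip_id == trip_id]
        if day_index is not None:
            out = [t for t in out if t.day_index == day_index]
        return out

    def write(self, out_dir: str | Path, overwrite: bool = False) -> Path:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()):
            if not overwrite:
                raise FileExistsError(f"{out} exists and is not empty; "
                                      "pass overwrite=True to replace it")
            shutil.rmtree(out)
        (out / "tracks").mkdir(parents=True, exist_ok=True)
        (out / "rasters").mkdir(parents=True, exist_ok=True)
        self.metadata.to_csv(out / "metadata.csv", index=False)
        for bird_id, df in self.tracks.items():
            d = df.copy()
            d["timestamp"] = pd.to_datetime(d.pop("t"), unit="s", utc=True).dt.strftime(
                "%Y-%m-%dT%H:%M:%SZ")
            d[["bird_id", "trip_hint", "timestamp", "lon", "lat"]].to_csv(
                out / "tracks" / f"{bird_id}.csv", index=False, float_format="%.7f")
        for name, rf in self.rasters.items():
            rf.to_csv_grid(out / "rasters" / f"{name}.csv")
        truth = {
            "config": {k: v for k, v in dataclasses.asdict(self.config).items()},
            "records": [t.to_dict() for t in self.truths],
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, sort_keys=True, indent=1, default=float)
        return out


def simulate_study(config: SimConfig, out_dir: str | Path | None = None,
                   overwrite: bool = False) -> StudyBundle:
    """Simulate a full study; optionally write it to a self-contained directory.

    Per bird: sex, nest stage and sampling period are assigned; trip count is
    truncated-geometric within ``trips_per_bird_range`` (mean ~2.2 at the
    default range); trip day counts follow ``day_mix``.  Colony attendance
    fixes separate consecutive trips so that trip splitting is non-trivial.
    """
    lo_trips, hi_trips = config.trips_per_bird_range
    periods = list(PERIOD_STARTS)
    weights = np.array([PERIOD_WEIGHTS[p] for p in periods])
    weights = weights / weights.sum()

    meta_rows = []
    tracks: dict[str, pd.DataFrame] = {}
    truths: list[TruthRecord] = []
    jitter = config.gps_noise_m

    for i in range(config.n_birds):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1, i)))
        bird_id = f"b{i:03d}"
        sex = "F" if rng.random() < 0.5 else "M"
        stage = "incubating" if rng.random() < 51 / 135 else "chick-rearing"
        period = periods[int(rng.choice(3, p=weights))]
        n_trips = int(np.clip(rng.geometric(1.0 / 2.2), lo_trips, hi_trips))
        t = (pd.Timestamp(PERIOD_STARTS[period], tz="UTC").timestamp()
             + rng.integers(0, 5) * 86400.0 + 12.0 * 3600.0)  # ~06:00 local
        parts = []
        for trip_id in range(n_trips):
            n_days = int(rng.choice([1, 2, 3], p=list(config.day_mix)))
            # brief colony attendance before departure
            att_t = t + np.arange(3) * 600.0
            ax = rng.normal(0.0, jitter, 3)
            ay = rng.normal(0.0, jitter, 3)
            alon, alat = config.projection.inverse(ax, ay)
            parts.append(pd.DataFrame({"bird_id": bird_id, "trip_hint": -1,
                                       "t": att_t, "lon": alon, "lat": alat}))
            t_depart = att_t[-1] + rng.uniform(600.0, 1800.0)
            trip_df, trip_truths = _simulate_trip(rng, config, bird_id, trip_id,
                                                  n_days, t_depart)
            parts.append(trip_df)
            truths.extend(trip_truths)
            # overnight at the colony before the next trip
            t = (np.floor(trip_df["t"].iloc[-1] / 86400.0) + 1) * 86400.0 + 12.0 * 3600.0
        tail_t = t + np.arange(2) * 600.0
        tx = rng.normal(0.0, jitter, 2)
        ty = rng.normal(0.0, jitter, 2)
        tlon, tlat = config.projection.inverse(tx, ty)
        parts.append(pd.DataFrame({"bird_id": bird_id, "trip_hint": -1,
                                   "t": tail_t, "lon": tlon, "lat": tlat}))
        tracks[bird_id] = pd.concat(parts, ignore_index=True)
        meta_rows.append({"bird_id": bird_id, "sex": sex, "nest_stage": stage,
                          "sampling_period": period, "n_trips": n_trips,
                          "fix_interval_s": config.fix_interval_s})

    metadata = pd.DataFrame(meta_rows)
    rasters = simulate_env_fields(config, truths)
    bundle = StudyBundle(config=config, metadata=metadata, tracks=tracks,
                         rasters=rasters, truths=truths)
    if out_dir is not None:
        bundle.write(out_dir, overwrite=overwrite)
    return bundle


def load_study(study_dir: str | Path) -> StudyBundle:
    """Read a study bundle written by :meth:`StudyBundle.write`."""
    d = Path(study_dir)
    with open(d / "truth.json") as fh:
        truth = json.load(fh)
    cfg_dict = dict(truth["config"])
    for key in ("trips_per_bird_range", "day_mix", "ars_patch_radii_m",
                "colony_lonlat", "domain_extent", "trip_range_km",
                "ars_bout_duration_s"):
        if key in cfg_dict and isinstance(cfg_dict[key], list):
            cfg_dict[key] = tuple(cfg_dict[key])
    for key in ("driver_vars",):
        if key in cfg_dict:
            cfg_dict[key] = {k: tuple(v) for k, v in cfg_dict[key].items()}
    for int_key in ("seed", "n_birds", "fix_interval_s", "ars_bouts_per_day",
                    "nested_sub_bouts"):
        cfg_dict[int_key] = int(cfg_dict[int_key])
    cfg_dict["trips_per_bird_range"] = tuple(int(v) for v in cfg_dict["trips_per_bird_range"])
    config = SimConfig(**cfg_dict)
    records = []
    for r in truth["records"]:
        bouts = [Bout(**{k: (int(v) if k in ("start_idx", "end_idx", "scale_rank")
                             else float(v)) for k, v in b.items()})
                 for b in r.pop("bouts")]
        records.append(TruthRecord(bird_id=r["bird_id"], trip_id=int(r["trip_id"]),
                                   day_index=int(r["day_index"]),
                                   n_fixes=int(r["n_fixes"]),
                                   t_first=float(r["t_first"]),
                                   t_last=float(r["t_last"]), bouts=bouts))
    metadata = pd.read_csv(d / "metadata.csv")
    tracks = {}
    for f in sorted((d / "tracks").glob("*.csv")):
        df = pd.read_csv(f)
        df["t"] = pd.to_datetime(df.pop("timestamp"), utc=True).astype("int64") / 1e9
        tracks[f.stem] = df[["bird_id", "trip_hint", "t", "lon", "lat"]]
    rasters = {}
    for f in sorted((d / "rasters").glob("*.csv")):
        rasters[f.stem] = RasterField.from_csv_grid(f)
    return StudyBundle(config=config, metadata=metadata, tracks=tracks,
                       rasters=rasters, truths=records)
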
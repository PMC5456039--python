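"""Environmental covariates: gridded fields, sampling, and track annotation.

Eleven oceanographic covariates are attached to every interpolated track
location: bathymetry, chlorophyll-a (8-day and monthly), mixed layer depth,
sea surface height anomaly (SSHA), sea surface temperature (daily, 8-day,
monthly), surface-current velocity, wind speed, and distance to the nearest
SST front.  The first ten are sampled from their own rasters by bilinear
interpolation at each raster's native resolution; distance-to-front is
derived from a front-probability raster by great-circle distance to the
nearest frontal cell.

Rasters are regular lon/lat grids (optionally stacked in time) held as
:class:`xarray.DataArray`; on disk they are plain CSV grids (first row lon
axis, first column lat axis) so a study bundle stays text-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .geo import haversine_m

#: the 11 model covariates, with units and the observed value range each
#: raster must stay inside (min, max).
VARIABLE_RANGES: dict[str, tuple[float, float]] = {
    "bathymetry": (-3788.0, -1.0),            # m
    "chla_8day": (0.05, 3.4),                 # mg/m^3
    "chla_monthly": (0.06, 2.9),              # mg/m^3
    "distance_to_front": (0.0, 142.0),        # km (derived from front layer)
    "mixed_layer_depth": (1.0, 97.8),         # m
    "ssha": (-0.1, 0.4),                      # m
    "sst_daily": (23.5, 28.2),                # deg C
    "sst_8day": (24.2, 28.0),                 # deg C
    "sst_monthly": (24.3, 28.2),              # deg C
    "velocity": (0.01, 0.2),                  # m/s
    "wind_speed": (2.2, 23.0),                # m/s
}

#: covariate columns of a finished annotation table, in canonical order
COVARIATES: tuple[str, ...] = tuple(VARIABLE_RANGES)

#: rasters sampled directly (everything except the derived distance-to-front)
GRIDDED_VARIABLES: tuple[str, ...] = tuple(
    v for v in VARIABLE_RANGES if v != "distance_to_front"
)

FRONT_LAYER = "front_probability"

#: half-cadence temporal matching windows, seconds
TIME_WINDOWS_S = {
    "wind_speed": 6 * 3600.0,
    "sst_daily": 12 * 3600.0,
    "ssha": 12 * 3600.0,
    "mixed_layer_depth": 12 * 3600.0,
    "chla_8day": 4 * 86400.0,
    "sst_8day": 4 * 86400.0,
    "velocity": 2.5 * 86400.0,
    "chla_monthly": 15 * 86400.0,
    "sst_monthly": 15 * 86400.0,
}


@dataclass
class RasterField:
    """A named regular lon/lat grid, optionally with a time axis.

    ``data`` has dims ("lat", "lon") or ("time", "lat", "lon"); lon/lat
    coordinates must be strictly monotone. Missing cells are NaN.
    """

    name: str
    data: xr.DataArray

    def __post_init__(self):
        dims = self.data.dims
        if dims not in (("lat", "lon"), ("time", "lat", "lon")):
            raise ValueError(f"raster dims must be (lat, lon) or (time, lat, lon), got {dims}")
        for ax in ("lon", "lat"):
            v = self.data.coords[ax].values
            d = np.diff(v)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{ax} axis must be strictly monotone")

    @property
    def has_time(self) -> bool:
        return "time" in self.data.dims

    # ------------------------------------------------------------------ io
    def to_csv_grid(self, path: str | Path) -> None:
        """Write as a CSV matrix: header row = lon axis, first column = lat axis."""
        if self.has_time:
            raise ValueError("CSV grid format holds a single layer; select a time first")
        df = pd.DataFrame(self.data.values,
                          index=self.data.coords["lat"].values,
                          columns=self.data.coords["lon"].values)
        df.index.name = "lat"
        df.to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv_grid(cls, path: str | Path, name: str | None = None) -> "RasterField":
        df = pd.read_csv(path, index_col=0)
        da = xr.DataArray(
            df.to_numpy(dtype=float),
            coords={"lat": df.index.to_numpy(dtype=float),
                    "lon": df.columns.to_numpy(dtype=float)},
            dims=("lat", "lon"),
        )
        return cls(name or Path(path).stem, da)

    # ------------------------------------------------------------ sampling
    def select_time(self, timestamp_s: float, window_s: float) -> "xr.DataArray | None":
        """Layer nearest ``timestamp_s`` within ``window_s``; earlier layer on ties.

        Returns None when no layer falls inside the window.
        """
        if not self.has_time:
            return self.data
        times = self.data.coords["time"].values.astype(float)
        if times.size == 0:
            raise ValueError("raster stack has an empty time axis")
        dt = np.abs(times - float(timestamp_s))
        i = int(np.argmin(dt))  # argmin returns the first (earlier) minimum
        if dt[i] > window_s:
            return None
        return self.data.isel(time=i)


def sample_bilinear(raster: RasterField | xr.DataArray, lon, lat) -> np.ndarray:
    """Bilinear interpolation of a single-layer raster at lon/lat points.

    Values are exact at grid nodes; NaN where the query point is outside the
    grid bounds or any of its four neighbouring cells is masked.
    """
    da = raster.data if isinstance(raster, RasterField) else raster
    if "time" in da.dims:
        raise ValueError("select a time layer before spatial sampling")
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    pts_lon = xr.DataArray(lon, dims="pt")
    pts_lat = xr.DataArray(lat, dims="pt")
    out = da.interp(lon=pts_lon, lat=pts_lat, method="linear").values
    n_oob = int(np.sum((lon < da.lon.values.min()) | (lon > da.lon.values.max())
                       | (lat < da.lat.values.min()) | (lat > da.lat.values.max())))
    if n_oob:
        warnings.warn(f"{n_oob} query point(s) outside raster bounds; returned NaN",
                      stacklevel=2)
    return out


def match_time(raster: RasterField, timestamp_s: float,
               window_s: float | None = None) -> "xr.DataArray | None":
    """Pick the raster layer temporally matching ``timestamp_s``.

    ``window_s`` defaults to the variable's half-cadence window (6 h for
    wind, 12 h for daily products, 4 d for 8-day, ~15 d for monthly).
    """
    if window_s is None:
        window_s = TIME_WINDOWS_S.get(raster.name, np.inf)
    return raster.select_time(timestamp_s, window_s)


def distance_to_front_km(front: RasterField | xr.DataArray, lon, lat,
                         threshold: float = 0.0) -> np.ndarray:
    """Great-circle distance (km) to the centre of the nearest frontal cell.

    A cell is frontal when its front probability exceeds ``threshold``
    (default: any positive probability). Zero for points whose own cell is
    frontal; NaN when the raster has no frontal cells.
    """
    da = front.data if isinstance(front, RasterField) else front
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    vals = da.values
    frontal = np.asarray(vals > threshold) & np.isfinite(vals)
    if not frontal.any():
        return np.full(lon.shape, np.nan)
    glat = da.coords["lat"].values
    glon = da.coords["lon"].values
    ii, jj = np.nonzero(frontal)
    flat, flon = glat[ii], glon[jj]
    # own-cell test: nearest grid node in each axis
    own_i = np.abs(lat[:, None] - glat[None, :]).argmin(axis=1)
    own_j = np.abs(lon[:, None] - glon[None, :]).argmin(axis=1)
    d = haversine_m(lon[:, None], lat[:, None], flon[None, :], flat[None, :])
    out = d.min(axis=1) / 1000.0
    out[frontal[own_i, own_j]] = 0.0
    return out


@dataclass
class AnnotationResult:
    """Annotated location table plus a per-variable completeness report."""

    table: pd.DataFrame
    completeness: pd.Series = field(repr=False)


def annotate(locations: pd.DataFrame, rasters: dict[str, RasterField],
             front_threshold: float = 0.0,
             time_column: str = "t") -> AnnotationResult:
    """Attach the 11 covariates to every location row.

    Parameters
    ----------
    locations : DataFrame with at least ``lon`` and ``lat`` columns; a time
        column (epoch seconds) is used for rasters that carry a time axis.
    rasters : mapping of variable name -> RasterField.  Expected keys are the
        ten :data:`GRIDDED_VARIABLES` plus ``front_probability``; a
        pre-computed ``distance_to_front`` raster, if supplied, is sampled
        instead of being derived.  Missing rasters leave their column NaN.
    """
    out = locations.copy()
    counts = {}
    lon = out["lon"].to_numpy(dtype=float)
    lat = out["lat"].to_numpy(dtype=float)
    times = out[time_column].to_numpy(dtype=float) if time_column in out else None

    for var in GRIDDED_VARIABLES:
        if var not in rasters:
            out[var] = np.nan
            counts[var] = 0.0
            continue
        rf = rasters[var]
        if rf.has_time:
            if times is None:
                raise ValueError(f"raster {var!r} has a time axis but locations "
                                 f"carry no {time_column!r} column")
            vals = np.full(len(out), np.nan)
            # resolve each location to a layer index, then sample each
            # matched layer once
            axis = rf.data.coords["time"].values.astype(float)
            window = TIME_WINDOWS_S.get(var, np.inf)
            dt = np.abs(times[:, None] - axis[None, :])
            layer_idx = dt.argmin(axis=1)
            layer_idx[dt[np.arange(len(times)), layer_idx] > window] = -1
            for li in np.unique(layer_idx):
                if li < 0:
                    continue
                sel = np.nonzero(layer_idx == li)[0]
                vals[sel] = sample_bilinear(rf.data.isel(time=int(li)), lon[sel], lat[sel])
        else:
            vals = sample_bilinear(rf, lon, lat)
        out[var] = vals
        counts[var] = float(np.mean(np.isfinite(vals))) if len(out) else 1.0

    if "distance_to_front" in rasters:
        dtf = sample_bilinear(rasters["distance_to_front"], lon, lat)
    elif FRONT_LAYER in rasters:
        dtf = distance_to_front_km(rasters[FRONT_LAYER], lon, lat,
                                   threshold=front_threshold)
    else:
        dtf = np.full(len(out), np.nan)
    out["distance_to_front"] = dtf
    counts["distance_to_front"] = float(np.mean(np.isfinite(dtf))) if len(out) else 1.0

    return AnnotationResult(table=out, completeness=pd.Series(counts).reindex(COVARIATES))
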
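"""Spherical geometry and the local planar projection used throughout.

All planar work in this package happens in a local azimuthal-equidistant
projection centred on the breeding colony: x is metres east, y metres north,
and every straight line through the origin preserves great-circle distance.
Within a few hundred kilometres of the centre (the foraging range of a
central-place seabird) planar distances agree with great-circle distances to
well under 0.1%.
"""

from __future__ import annotations

import warnings

import numpy as np

EARTH_RADIUS_M = 6371008.8  # mean Earth radius


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres between points given in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing, geographic degrees clockwise from North in [0, 360)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    x = np.sin(dlon) * np.cos(lat2)
    y = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    out = np.mod(np.degrees(np.arctan2(x, y)), 360.0)
    return np.where(out >= 360.0, 0.0, out)  # guard the -0.0 wrap


def destination_point(lon, lat, bearing_deg, distance_m):
    """Point reached travelling ``distance_m`` along ``bearing_deg`` on the sphere."""
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    theta = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_m, dtype=float) / EARTH_RADIUS_M
    lat2 = np.arcsin(np.sin(lat1) * np.cos(delta)
                     + np.cos(lat1) * np.sin(delta) * np.cos(theta))
    lon2 = lon1 + np.arctan2(np.sin(theta) * np.sin(delta) * np.cos(lat1),
                             np.cos(delta) - np.sin(lat1) * np.sin(lat2))
    return np.degrees(lon2), np.degrees(lat2)


class LocalProjection:
    """Azimuthal-equidistant projection about a fixed centre (the colony).

    Parameters
    ----------
    lon0, lat0 : float
        Projection centre in degrees (WGS84 lon/lat).
    """

    def __init__(self, lon0: float, lat0: float):
        if not (-180.0 <= lon0 <= 180.0) or not (-90.0 < lat0 < 90.0):
            raise ValueError("projection centre must have |lon|<=180 and |lat|<90")
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)

    def forward(self, lon, lat):
        """Project lon/lat (degrees) to planar x, y in metres."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any(np.abs(lat) >= 90.0):
            raise ValueError("latitude at or beyond the pole is outside the projection domain")
        span = np.max(lon, initial=self.lon0) - np.min(lon, initial=self.lon0)
        if span > 6.0:
            warnings.warn("fixes span more than 6 deg longitude; projection distortion "
                          "may exceed the stated accuracy", stacklevel=2)
        d = haversine_m(self.lon0, self.lat0, lon, lat)
        theta = np.radians(initial_bearing_deg(self.lon0, self.lat0, lon, lat))
        return d * np.sin(theta), d * np.cos(theta)

    def inverse(self, x, y):
        """Planar metres back to lon/lat degrees (exact inverse on the sphere)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        d = np.hypot(x, y)
        bearing = np.degrees(np.arctan2(x, y))
        lon, lat = destination_point(self.lon0, self.lat0, bearing, d)
        # at d == 0 the bearing is undefined; destination_point already
        # returns the centre there.
        return lon, lat


def circular_mean_deg(angles_deg):
    """Circular mean of angles in degrees, result in [0, 360). NaN for empty input."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        return float("nan")
    s, c = np.mean(np.sin(a)), np.mean(np.cos(a))
    out = float(np.mod(np.degrees(np.arctan2(s, c)), 360.0))
    return 0.0 if out >= 360.0 else out
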
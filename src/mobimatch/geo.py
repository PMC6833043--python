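"""Spherical geometry helpers.

All distances use the haversine formula on a sphere with the IUGG mean
Earth radius; at the sub-kilometre scales of home buffers and stop
clusters this is accurate to well under a metre, with no projection
dependency.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8  # IUGG mean Earth radius (6371.0088 km)


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres between WGS84 points (degrees).

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    return _haversine_rad(lat1, lon1, lat2, lon2)


def _haversine_rad(lat1, lon1, lat2, lon2):
    """Haversine distance (m) for coordinates already in radians."""
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def offset_deg(lat_deg, north_m, east_m):
    """Convert a metric (north, east) offset into (dlat, dlon) degrees.

    The conversion is anchored at latitude ``lat_deg`` so the offset is
    isotropic in metres in the local tangent frame.
    """
    lat_deg = np.asarray(lat_deg, dtype=float)
    dlat = np.degrees(np.asarray(north_m, dtype=float) / EARTH_RADIUS_M)
    dlon = np.degrees(np.asarray(east_m, dtype=float)
                      / (EARTH_RADIUS_M * np.cos(np.radians(lat_deg))))
    return dlat, dlon


def destination_point(lat_deg, lon_deg, bearing_deg, dist_m):
    """Great-circle destination from a point given bearing and distance."""
    lat1 = np.radians(lat_deg)
    lon1 = np.radians(lon_deg)
    brg = np.radians(bearing_deg)
    sigma = np.asarray(dist_m, dtype=float) / EARTH_RADIUS_M
    lat2 = np.arcsin(np.sin(lat1) * np.cos(sigma)
                     + np.cos(lat1) * np.sin(sigma) * np.cos(brg))
    lon2 = lon1 + np.arctan2(np.sin(brg) * np.sin(sigma) * np.cos(lat1),
                             np.cos(sigma) - np.sin(lat1) * np.sin(lat2))
    return np.degrees(lat2), np.degrees(lon2)


def interpolate_great_circle(lat1, lon1, lat2, lon2, frac):
    """Points along the great circle from P1 to P2 at fractions ``frac``.

    Spherical linear interpolation on unit vectors; degenerate
    (coincident) endpoints fall back to the start point.
    """
    frac = np.atleast_1d(np.asarray(frac, dtype=float))

    def unit(lat, lon):
        la, lo = np.radians(lat), np.radians(lon)
        return np.array([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)])

    v1 = unit(lat1, lon1)
    v2 = unit(lat2, lon2)
    omega = np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0))
    if omega < 1e-12:
        pts = np.repeat(v1[None, :], len(frac), axis=0)
    else:
        s = np.sin(omega)
        pts = (np.sin((1.0 - frac)[:, None] * omega) * v1[None, :]
               + np.sin(frac[:, None] * omega) * v2[None, :]) / s
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    lat = np.degrees(np.arcsin(np.clip(pts[:, 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
    return lat, lon
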
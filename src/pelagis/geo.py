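"""Spherical geodesy helpers: haversine distance and the azimuthal equidistant
projection used as the planar working frame around the colony.

Spherical Earth, mean radius 6371.0088 km; coordinates decimal degrees WGS84-style
(longitude west-negative).  The azimuthal equidistant projection preserves both
distance and azimuth from its origin exactly, which is the property the kernel /
rotation analyses rely on.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points given in decimal degrees."""
    p1, l1, p2, l2 = (np.deg2rad(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    a = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2) ** 2
    return 2 * EARTH_RADIUS_M / 1000.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def azimuthal_equidistant_forward(lat, lon, lat0: float, lon0: float):
    """Project (lat, lon) to planar (x, y) metres about origin (lat0, lon0)."""
    phi = np.deg2rad(np.asarray(lat, dtype=float))
    lam = np.deg2rad(np.asarray(lon, dtype=float))
    phi0, lam0 = np.deg2rad(lat0), np.deg2rad(lon0)
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    # k = c / sin(c); limit 1 at the origin
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
    x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_M * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0))
    return x, y


def azimuthal_equidistant_inverse(x, y, lat0: float, lon0: float):
    """Inverse of :func:`azimuthal_equidistant_forward`; returns (lat, lon) degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    phi0, lam0 = np.deg2rad(lat0), np.deg2rad(lon0)
    rho = np.hypot(x, y)
    c = rho / EARTH_RADIUS_M
    safe_rho = np.where(rho > 1e-9, rho, 1.0)
    phi = np.where(
        rho > 1e-9,
        np.arcsin(np.clip(np.cos(c) * np.sin(phi0) + y * np.sin(c) * np.cos(phi0) / safe_rho, -1.0, 1.0)),
        phi0,
    )
    lam = np.where(
        rho > 1e-9,
        lam0 + np.arctan2(x * np.sin(c), safe_rho * np.cos(c) * np.cos(phi0) - y * np.sin(c) * np.sin(phi0)),
        lam0,
    )
    lat = np.rad2deg(phi)
    lon = normalize_longitude(np.rad2deg(lam))
    return lat, lon


def normalize_longitude(lon):
    """Normalize longitudes to (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    out = -(np.mod(-lon + 180.0, 360.0) - 180.0)
    return out
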
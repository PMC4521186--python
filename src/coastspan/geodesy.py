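"""Spherical-earth distance helpers.

All along-coast and point-to-coast distances in the package are great-circle
distances on a sphere of radius :data:`EARTH_RADIUS_KM`. The constant is fixed
(not configurable) so that measured ranges are bit-stable across runs.
"""

from __future__ import annotations

import numpy as np

#: Mean Earth radius, km. Fixed package-wide.
EARTH_RADIUS_KM = 6371.0


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any((lon < -180.0) | (lon >= 180.0 + 1e-9)):
        raise ValueError("longitude out of range [-180, 180)")


def great_circle_km(a, b):
    """Great-circle distance between two (lat, lon) points in degrees, in km.

    Accepts scalars or broadcastable arrays. Uses the haversine formula,
    which is symmetric, non-negative and numerically safe for small
    separations.
    """
    lat1, lon1 = a
    lat2, lon2 = b
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1 = np.radians(np.asarray(lat1, dtype=float))
    phi2 = np.radians(np.asarray(lat2, dtype=float))
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    h = np.clip(h, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
    if np.ndim(d) == 0:
        return float(d)
    return d


def to_unit_vectors(lat, lon) -> np.ndarray:
    """Convert degree coordinates to 3-D unit vectors, shape (..., 3)."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    return np.stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)], axis=-1
    )


def from_unit_vectors(v: np.ndarray):
    """Inverse of :func:`to_unit_vectors`; returns (lat, lon) in degrees."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    u = v / n
    lat = np.degrees(np.arcsin(np.clip(u[..., 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(u[..., 1], u[..., 0]))
    # keep the [-180, 180) convention used throughout
    lon = np.where(lon >= 180.0, lon - 360.0, lon)
    return lat, lon


def unit_vector_distance_km(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Great-circle distance between unit vectors (broadcasting), km."""
    # atan2 form: accurate at both small and antipodal separations
    cross = np.linalg.norm(np.cross(u, v), axis=-1)
    dot = np.sum(u * v, axis=-1)
    return EARTH_RADIUS_KM * np.arctan2(cross, dot)
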
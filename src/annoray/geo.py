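"""Local ENU frame <-> WGS84 geodetic coordinates.

The photogrammetric model lives in a local metric Cartesian frame.  We
declare that frame to be east-north-up (ENU) tangent to the WGS84
ellipsoid at an anchor point supplied in the survey configuration, and
convert through Earth-centered Earth-fixed (ECEF) coordinates:

    local ENU  ->  ECEF  ->  geodetic (lat, lon, h)

Heights are ellipsoidal; the depth of a seafloor point is ``-h`` relative
to the ellipsoid.  For exports in a projected CRS instead of ENU, a
"projected" mode interprets local x/y directly as easting/northing offsets
from the anchor's projected position (a pluggable affine, not a full CRS
engine).

WGS84 constants: a = 6378137 m, 1/f = 298.257223563.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeoAnchor",
    "WGS84_A",
    "WGS84_F",
    "geodetic_to_ecef",
    "ecef_to_geodetic",
    "enu_rotation",
    "local_to_geodetic",
    "geodetic_to_local",
]

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
_E2 = WGS84_F * (2.0 - WGS84_F)  # first eccentricity squared


@dataclass(frozen=True)
class GeoAnchor:
    """Geodetic position of the local-frame origin; local axes are ENU here."""

    lat0: float  # degrees
    lon0: float  # degrees
    h0: float = 0.0  # ellipsoidal height, meters

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat0 <= 90.0):
            raise ValueError(f"anchor latitude out of range: {self.lat0}")
        if not (-180.0 <= self.lon0 <= 180.0):
            raise ValueError(f"anchor longitude out of range: {self.lon0}")


def geodetic_to_ecef(lat_deg, lon_deg, h) -> np.ndarray:
    """WGS84 geodetic -> ECEF (meters).  Accepts scalars or arrays."""
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    lon = np.radians(np.asarray(lon_deg, dtype=float))
    h = np.asarray(h, dtype=float)
    sin_lat, cos_lat = np.sin(lat), np.cos(lat)
    n = WGS84_A / np.sqrt(1.0 - _E2 * sin_lat**2)
    x = (n + h) * cos_lat * np.cos(lon)
    y = (n + h) * cos_lat * np.sin(lon)
    z = (n * (1.0 - _E2) + h) * sin_lat
    return np.stack([x, y, z], axis=-1)


def ecef_to_geodetic(xyz: np.ndarray, tol_m: float = 1e-9, max_iter: int = 20) -> np.ndarray:
    """ECEF -> WGS84 geodetic ``(lat deg, lon deg, h m)``.

    Bowring's closed form provides the start; fixed-point refinement of the
    latitude continues until the height update falls below ``tol_m``.
    """
    xyz = np.asarray(xyz, dtype=float)
    single = xyz.ndim == 1
    xyz = np.atleast_2d(xyz)
    x, y, z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    lon = np.arctan2(y, x)
    p = np.hypot(x, y)

    b = WGS84_A * (1.0 - WGS84_F)
    ep2 = (WGS84_A**2 - b**2) / b**2
    theta = np.arctan2(z * WGS84_A, p * b)
    lat = np.arctan2(z + ep2 * b * np.sin(theta) ** 3, p - _E2 * WGS84_A * np.cos(theta) ** 3)

    h = np.zeros_like(p)
    for _ in range(max_iter):
        sin_lat = np.sin(lat)
        cos_lat = np.cos(lat)
        n = WGS84_A / np.sqrt(1.0 - _E2 * sin_lat**2)
        off_pole = np.abs(cos_lat) > 1e-10
        h_new = np.where(
            off_pole,
            p / np.where(off_pole, cos_lat, 1.0) - n,
            np.abs(z) / np.maximum(np.abs(sin_lat), 1e-10) - n * (1.0 - _E2),
        )
        lat = np.arctan2(z, p * (1.0 - _E2 * n / (n + h_new)))
        if np.all(np.abs(h_new - h) < tol_m):
            h = h_new
            break
        h = h_new
    out = np.stack([np.degrees(lat), np.degrees(lon), h], axis=-1)
    return out[0] if single else out


def enu_rotation(anchor: GeoAnchor) -> np.ndarray:
    """Matrix whose columns are the ECEF unit vectors east, north, up at the anchor."""
    lat = np.radians(anchor.lat0)
    lon = np.radians(anchor.lon0)
    sl, cl = np.sin(lat), np.cos(lat)
    so, co = np.sin(lon), np.cos(lon)
    east = np.array([-so, co, 0.0])
    north = np.array([-sl * co, -sl * so, cl])
    up = np.array([cl * co, cl * so, sl])
    return np.column_stack([east, north, up])


def local_to_geodetic(p_local: np.ndarray, anchor: GeoAnchor) -> np.ndarray:
    """Local ENU meters -> ``(lat deg, lon deg, h m)``; scalar or array of points."""
    p = np.asarray(p_local, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    ecef0 = geodetic_to_ecef(anchor.lat0, anchor.lon0, anchor.h0)
    ecef = ecef0[None, :] + p @ enu_rotation(anchor).T
    out = ecef_to_geodetic(ecef)
    return out[0] if single else out


def geodetic_to_local(lat_deg, lon_deg, h, anchor: GeoAnchor) -> np.ndarray:
    """Inverse of :func:`local_to_geodetic`; scalars or arrays."""
    ecef0 = geodetic_to_ecef(anchor.lat0, anchor.lon0, anchor.h0)
    ecef = geodetic_to_ecef(lat_deg, lon_deg, h)
    return (ecef - ecef0) @ enu_rotation(anchor)
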
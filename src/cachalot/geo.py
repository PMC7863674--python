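"""Spherical-earth geometry: great-circle distances and an equal-area projection.

All distances are in kilometres on a sphere of radius 6,371 km. The
Lambert azimuthal equal-area projection is used wherever areas or
densities are computed, because geographic degrees are anisotropic at
the study latitudes (~20°S: 1° of longitude spans ~104 km, 1° of
latitude ~111 km).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0
#: km per degree of latitude (and of longitude at the equator)
KM_PER_DEGREE = EARTH_RADIUS_KM * np.pi / 180.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance between points in decimal degrees.

    Accepts scalars or broadcastable arrays; returns km.

    Raises
    ------
    ValueError
        If any coordinate is outside [-180, 180] x [-90, 90].
    """
    lon1, lat1, lon2, lat2 = (np.asarray(v, dtype=float) for v in (lon1, lat1, lon2, lat2))
    for lon, lat in ((lon1, lat1), (lon2, lat2)):
        if np.any(np.abs(lon) > 180.0) or np.any(np.abs(lat) > 90.0):
            raise ValueError("coordinates outside valid lon/lat range")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


class AzimuthalEqualArea:
    """Lambert azimuthal equal-area projection centred on (lon0, lat0).

    Forward maps lon/lat degrees to (x, y) in km; the projection preserves
    areas exactly on the sphere, so km² measured on the projected plane are
    true spherical areas.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._phi0 = np.radians(lat0)

    @classmethod
    def centred_on(cls, lons, lats) -> "AzimuthalEqualArea":
        return cls(float(np.mean(lons)), float(np.mean(lats)))

    def forward(self, lons, lats):
        lam = np.radians(np.asarray(lons, dtype=float)) - np.radians(self.lon0)
        phi = np.radians(np.asarray(lats, dtype=float))
        phi0 = self._phi0
        denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
        # antipode maps to infinity; points there are outside any sane study area
        k = np.sqrt(2.0 / np.maximum(denom, 1e-12))
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam)
        y = EARTH_RADIUS_KM * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam)
        )
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
        phi0 = self._phi0
        with np.errstate(invalid="ignore"):
            phi = np.where(
                rho == 0,
                phi0,
                np.arcsin(np.clip(
                    np.cos(c) * np.sin(phi0) + y * np.sin(c) * np.cos(phi0) / np.where(rho == 0, 1.0, rho),
                    -1.0, 1.0,
                )),
            )
            lam = np.where(
                rho == 0,
                0.0,
                np.arctan2(
                    x * np.sin(c),
                    rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c),
                ),
            )
        return np.degrees(lam) + self.lon0, np.degrees(phi)
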
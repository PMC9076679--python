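"""Planar projection of geographic coordinates.

Tracks spanning ~15°S to 65°S are projected onto a plane so that movement
can be modelled in kilometres. An azimuthal equidistant projection on the
sphere keeps distances from the projection centre exact and distorts
chords between nearby points only mildly over the study span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class AzimuthalEquidistant:
    """Spherical azimuthal equidistant projection, units of km.

    Parameters
    ----------
    lon0, lat0 : float
        Projection centre in degrees. The default centre (40°W, 45°S)
        sits mid-way along a Brazil → Scotia Sea migration corridor.
    k0 : float
        Secant scale factor (as in UTM's 0.9996): pure azimuthal
        equidistant charts stretch chords transverse to the centre
        direction by c/sin(c); shrinking the map slightly balances the
        error so distances ~10° from the centre (e.g. along 55°S, the
        feeding-ground latitudes) stay within 0.5% of great-circle.
    """

    lon0: float = -40.0
    lat0: float = -45.0
    radius_km: float = EARTH_RADIUS_KM
    k0: float = 0.9974

    def forward(self, lon, lat):
        """Project lon/lat (degrees) to x/y (km). Accepts scalars or arrays."""
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        lam0, phi0 = np.radians(self.lon0), np.radians(self.lat0)
        dlam = lam - lam0
        cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        # antipode of the centre has no unique azimuth
        if np.any(c > np.pi - 1e-9):
            raise ValueError("point at or near the projection antipode")
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        r = self.radius_km * self.k0
        x = r * k * np.cos(phi) * np.sin(dlam)
        y = r * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam)
        )
        return x, y

    def inverse(self, x, y):
        """Inverse projection of x/y (km) back to lon/lat (degrees)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lam0, phi0 = np.radians(self.lon0), np.radians(self.lat0)
        rho = np.hypot(x, y)
        c = rho / (self.radius_km * self.k0)
        safe_rho = np.where(rho > 1e-12, rho, 1.0)
        sin_c, cos_c = np.sin(c), np.cos(c)
        phi = np.arcsin(
            np.clip(cos_c * np.sin(phi0) + y * sin_c * np.cos(phi0) / safe_rho, -1, 1)
        )
        lam = lam0 + np.arctan2(
            x * sin_c, safe_rho * cos_c * np.cos(phi0) - y * sin_c * np.sin(phi0)
        )
        lon = np.degrees(np.where(rho > 1e-12, lam, lam0))
        lat = np.degrees(np.where(rho > 1e-12, phi, phi0))
        return lon, lat


def haversine_km(lon1, lat1, lon2, lat2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between points given in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dphi = lat2 - lat1
    dlam = lon2 - lon1
    a = np.sin(dphi / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlam / 2) ** 2
    return 2 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
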
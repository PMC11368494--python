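"""Spherical geometry and an equal-area map projection.

All distances in this package are great-circle (haversine) distances on a
sphere of radius 6371.0088 km; at goose-migration scales the ~8 m device
error dwarfs spheroid corrections. Gridded analyses (utilization
distributions, area accounting) use an Albers equal-area conic projection
for North America, because per-cell areas must be honest km².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Mean Earth radius (IUGG), km.
EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance between WGS84 points, km. Vectorized."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def initial_bearing_rad(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2, radians from north."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.arctan2(y, x)


@dataclass(frozen=True)
class AlbersEqualArea:
    """Albers equal-area conic projection on the sphere (Snyder 1987, §14).

    Defaults are a standard North-America setup: standard parallels 20°/60°,
    origin (40° N, 96° W). Coordinates are in km.
    """

    lat1_deg: float = 20.0
    lat2_deg: float = 60.0
    lat0_deg: float = 40.0
    lon0_deg: float = -96.0
    radius_km: float = EARTH_RADIUS_KM

    @property
    def _n(self) -> float:
        p1, p2 = np.radians([self.lat1_deg, self.lat2_deg])
        return 0.5 * (np.sin(p1) + np.sin(p2))

    @property
    def _C(self) -> float:
        p1 = np.radians(self.lat1_deg)
        return np.cos(p1) ** 2 + 2.0 * self._n * np.sin(p1)

    def _rho(self, lat_rad):
        return self.radius_km / self._n * np.sqrt(self._C - 2.0 * self._n * np.sin(lat_rad))

    def forward(self, lon, lat):
        """(lon, lat) degrees -> (x, y) km. Vectorized."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        n = self._n
        theta = n * np.radians(lon - self.lon0_deg)
        rho = self._rho(np.radians(lat))
        rho0 = self._rho(np.radians(self.lat0_deg))
        return rho * np.sin(theta), rho0 - rho * np.cos(theta)

    def inverse(self, x, y):
        """(x, y) km -> (lon, lat) degrees. Vectorized."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = self._n
        rho0 = self._rho(np.radians(self.lat0_deg))
        rho = np.hypot(x, rho0 - y)
        theta = np.arctan2(x, rho0 - y)
        sin_lat = (self._C - (rho * n / self.radius_km) ** 2) / (2.0 * n)
        lat = np.degrees(np.arcsin(np.clip(sin_lat, -1.0, 1.0)))
        lon = self.lon0_deg + np.degrees(theta / n)
        return lon, lat

    @property
    def proj_string(self) -> str:
        return (f"+proj=aea +lat_1={self.lat1_deg} +lat_2={self.lat2_deg} "
                f"+lat_0={self.lat0_deg} +lon_0={self.lon0_deg} "
                f"+R={self.radius_km * 1000.0} +units=km +no_defs")


def destination_point(lon, lat, bearing_rad, distance_km):
    """Point reached from (lon, lat) on the given initial bearing and distance."""
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    brg = np.asarray(bearing_rad, dtype=float)
    lat2 = np.arcsin(np.sin(lat1) * np.cos(delta)
                     + np.cos(lat1) * np.sin(delta) * np.cos(brg))
    lon2 = lon1 + np.arctan2(np.sin(brg) * np.sin(delta) * np.cos(lat1),
                             np.cos(delta) - np.sin(lat1) * np.sin(lat2))
    lon2 = (lon2 + np.pi) % (2.0 * np.pi) - np.pi
    return np.degrees(lon2), np.degrees(lat2)
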
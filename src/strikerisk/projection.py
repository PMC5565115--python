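"""Albers equal-area conic projection (spherical form).

Vessel positions arrive as WGS84 longitude/latitude; all geometry
(track clipping, cell areas, kriging distances) runs in a projected
plane. An equal-area projection keeps cell areas honest, which matters
because expected whale abundance per cell is density x cell area.

The spherical closed form is used with the authalic earth radius; over
a coastal study region a few hundred kilometers across, the departure
from the ellipsoidal projection is far below the ~12-km cell scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_M = 6_371_007.2  # authalic radius


@dataclass(frozen=True)
class AlbersEqualArea:
    """Forward/inverse Albers projection with configurable parallels.

    Defaults are suited to the U.S. West Coast (the conventional
    CONUS-Albers parallels).
    """

    lon_origin: float = -125.0
    lat_origin: float = 37.0
    std_parallel_1: float = 33.0
    std_parallel_2: float = 45.0
    radius: float = EARTH_RADIUS_M

    @property
    def _n(self) -> float:
        p1, p2 = np.radians(self.std_parallel_1), np.radians(self.std_parallel_2)
        return (np.sin(p1) + np.sin(p2)) / 2.0

    @property
    def _c(self) -> float:
        p1 = np.radians(self.std_parallel_1)
        return np.cos(p1) ** 2 + 2.0 * self._n * np.sin(p1)

    def _rho(self, lat_rad):
        n = self._n
        return self.radius * np.sqrt(np.maximum(self._c - 2.0 * n * np.sin(lat_rad), 0.0)) / n

    def forward(self, lon, lat):
        """Project lon/lat (degrees) to x/y meters."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        n = self._n
        theta = n * np.radians(lon - self.lon_origin)
        rho = self._rho(np.radians(lat))
        rho0 = self._rho(np.radians(self.lat_origin))
        x = rho * np.sin(theta)
        y = rho0 - rho * np.cos(theta)
        return x, y

    def inverse(self, x, y):
        """Unproject x/y meters back to lon/lat degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = self._n
        rho0 = self._rho(np.radians(self.lat_origin))
        rho = np.hypot(x, rho0 - y)
        theta = np.arctan2(x, rho0 - y)
        lat = np.degrees(np.arcsin(np.clip((self._c - (rho * n / self.radius) ** 2) / (2.0 * n), -1.0, 1.0)))
        lon = self.lon_origin + np.degrees(theta / n)
        return lon, lat
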
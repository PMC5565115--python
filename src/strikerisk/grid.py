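"""Square analysis grid in projected coordinates.

The study region is discretized into equal square cells (default
12 km x 12 km, i.e. ~144 km^2) indexed row-major by integer cell id.
All per-cell model inputs (kriged vessel fields, track statistics,
whale abundance) and outputs (expected mortality) are keyed by cell id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box, mapping


@dataclass(frozen=True)
class AnalysisGrid:
    """Regular square grid on a projected plane.

    Parameters
    ----------
    x0, y0:
        Projected coordinates (meters) of the lower-left corner.
    nx, ny:
        Number of columns / rows.
    cell_size:
        Cell edge length in meters (default 12 km).
    """

    x0: float
    y0: float
    nx: int
    ny: int
    cell_size: float = 12_000.0

    def __post_init__(self):
        if self.nx <= 0 or self.ny <= 0 or self.cell_size <= 0:
            raise ValueError("grid dimensions and cell size must be positive")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size ** 2

    @property
    def cell_area_km2(self) -> float:
        return self.cell_area_m2 * 1e-6

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.cell_size,
            self.y0 + self.ny * self.cell_size,
        )

    def cell_origin(self, cell_id: int) -> tuple[float, float]:
        row, col = divmod(int(cell_id), self.nx)
        return self.x0 + col * self.cell_size, self.y0 + row * self.cell_size

    def cell_polygon(self, cell_id: int):
        cx, cy = self.cell_origin(cell_id)
        return box(cx, cy, cx + self.cell_size, cy + self.cell_size)

    def cell_polygons(self):
        return [self.cell_polygon(i) for i in range(self.n_cells)]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of x and y center coordinates, index-aligned with cell id."""
        ids = np.arange(self.n_cells)
        rows, cols = np.divmod(ids, self.nx)
        x = self.x0 + (cols + 0.5) * self.cell_size
        y = self.y0 + (rows + 0.5) * self.cell_size
        return x, y

    def locate(self, x, y) -> np.ndarray:
        """Cell ids containing points (x, y); -1 for points off the grid.

        Points exactly on an interior edge belong to the cell above/right
        (half-open convention); the top/right boundary is closed so the
        grid's own corners stay inside.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((y - self.y0) / self.cell_size).astype(int)
        xmax = self.x0 + self.nx * self.cell_size
        ymax = self.y0 + self.ny * self.cell_size
        col = np.where(np.isclose(x, xmax), self.nx - 1, col)
        row = np.where(np.isclose(y, ymax), self.ny - 1, row)
        inside = (col >= 0) & (col < self.nx) & (row >= 0) & (row < self.ny)
        return np.where(inside, row * self.nx + col, -1)

    def to_geojson(self) -> dict:
        feats = []
        for i in range(self.n_cells):
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"cell_id": i, "area_km2": self.cell_area_km2},
                    "geometry": mapping(self.cell_polygon(i)),
                }
            )
        return {"type": "FeatureCollection", "features": feats}

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)
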
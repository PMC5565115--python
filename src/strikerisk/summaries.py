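"""Spatial summaries of mortality surfaces.

High-risk area delineation (above-mean and above-90th-percentile masks),
zonal statistics over management jurisdictions (total deaths, deaths per
10^4 km^2, share of study-area total), continental-shelf partition, and
comparison against the Potential Biological Removal limit.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.ops import unary_union

from .core import MortalitySurface, SpeciesParams

log = logging.getLogger(__name__)

__all__ = [
    "Jurisdiction",
    "JurisdictionSet",
    "ZonalSummary",
    "threshold_mask",
    "zonal_summary",
    "pbr_comparison",
    "shelf_partition",
]


@dataclass(frozen=True)
class Jurisdiction:
    name: str
    category: str          # BIA | TSS | NMS | state_waters | shelf | custom
    geometry: object       # shapely polygon in the grid's projected CRS

    @property
    def area_km2(self) -> float:
        return self.geometry.area * 1e-6


@dataclass
class JurisdictionSet:
    zones: list[Jurisdiction]

    def __post_init__(self):
        seen = set()
        for z in self.zones:
            key = (z.category, z.name)
            if key in seen:
                raise ValueError(f"duplicate zone name within category: {key}")
            seen.add(key)
            if z.geometry.area <= 0:
                raise ValueError(f"zone {z.name} has non-positive area")

    @classmethod
    def from_geojson(cls, path) -> "JurisdictionSet":
        with open(path) as fh:
            gj = json.load(fh)
        zones = [
            Jurisdiction(
                name=f["properties"].get("name", f"zone{i}"),
                category=f["properties"].get("category", "custom"),
                geometry=shape(f["geometry"]),
            )
            for i, f in enumerate(gj["features"])
        ]
        return cls(zones)

    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"name": z.name, "category": z.category},
                    "geometry": mapping(z.geometry),
                }
                for z in self.zones
            ],
        }


@dataclass(frozen=True)
class ZonalSummary:
    zone: str
    area_km2: float
    total_mortality: float
    intensity: float          # deaths per 10^4 km^2
    percent_of_total: float   # proportion in [0, 1]


def threshold_mask(surface: MortalitySurface, mode: str = "above_p90") -> dict:
    """Cells with mortality above the mean or the 90th percentile.

    Percentile is taken over all cell values, unweighted, with linear
    interpolation; the mask is strictly-above (so a constant surface
    yields an empty above-mean mask). Returns the boolean mask, the
    dissolved polygon, and {area_km2, mortality_sum, percent_of_total}.
    """
    vals = surface.values
    if surface.total == 0.0:
        warnings.warn("threshold_mask: all-zero surface; empty mask")
        thr = 0.0
    elif mode == "above_mean":
        thr = float(vals.mean())
    elif mode == "above_p90":
        thr = float(np.percentile(vals, 90))
    else:
        raise ValueError(f"unknown threshold mode: {mode!r}")
    mask = vals > thr
    polys = [surface.grid.cell_polygon(i) for i in np.flatnonzero(mask)]
    geom = unary_union(polys) if polys else None
    msum = float(vals[mask].sum())
    return {
        "mode": mode,
        "threshold": thr,
        "mask": mask,
        "polygons": geom,
        "area_km2": float(mask.sum() * surface.grid.cell_area_km2),
        "mortality_sum": msum,
        "percent_of_total": msum / surface.total if surface.total > 0 else 0.0,
    }


def _overlap_fractions(surface: MortalitySurface, geometry, rule: str) -> np.ndarray:
    """Fraction of each cell's area inside a zone geometry."""
    grid = surface.grid
    frac = np.zeros(grid.n_cells)
    minx, miny, maxx, maxy = geometry.bounds
    c0 = max(int((minx - grid.x0) // grid.cell_size), 0)
    c1 = min(int((maxx - grid.x0) // grid.cell_size), grid.nx - 1)
    r0 = max(int((miny - grid.y0) // grid.cell_size), 0)
    r1 = min(int((maxy - grid.y0) // grid.cell_size), grid.ny - 1)
    if c0 > c1 or r0 > r1:
        return frac
    for row in range(r0, r1 + 1):
        for col in range(c0, c1 + 1):
            cid = row * grid.nx + col
            cell = grid.cell_polygon(cid)
            if rule == "center":
                frac[cid] = 1.0 if geometry.contains(cell.centroid) else 0.0
            else:
                inter = cell.intersection(geometry)
                frac[cid] = inter.area / cell.area if not inter.is_empty else 0.0
    return frac


def zonal_summary(
    surface: MortalitySurface,
    zones: JurisdictionSet,
    overlap_rule: str = "area",
) -> list[ZonalSummary]:
    """Zonal statistics: total deaths, deaths/10^4 km^2, share of total.

    Cell mortality is apportioned to a zone by the fraction of the cell's
    area inside the zone (``overlap_rule='area'``, exact polygon
    intersection) or all-or-nothing by cell center (``'center'``).
    """
    total = surface.total
    out = []
    for z in zones.zones:
        frac = _overlap_fractions(surface, z.geometry, overlap_rule)
        if frac.sum() == 0.0:
            log.info("zonal_summary: zone %s does not overlap the grid", z.name)
        m = float((surface.values * frac).sum())
        area = z.area_km2
        out.append(
            ZonalSummary(
                zone=z.name,
                area_km2=area,
                total_mortality=m,
                intensity=m / (area / 1e4) if area > 0 else 0.0,
                percent_of_total=m / total if total > 0 else 0.0,
            )
        )
    return out


def pbr_comparison(total_mortality: float, species: SpeciesParams) -> float:
    """Ratio of estimated mortality to the Potential Biological Removal limit."""
    return total_mortality / species.pbr


def shelf_partition(
    surface: MortalitySurface,
    depth_m: np.ndarray,
    threshold: float = 200.0,
) -> dict[str, ZonalSummary]:
    """Split mortality on/off the continental shelf (< threshold depth).

    ``depth_m`` is positive water depth per cell; missing (NaN) depths are
    assigned off-shelf with a warning. The partition is exhaustive and
    exclusive, so the two totals sum to the surface total.
    """
    depth_m = np.asarray(depth_m, dtype=float)
    if depth_m.shape != (surface.grid.n_cells,):
        raise ValueError("bathymetry must cover every grid cell")
    missing = np.isnan(depth_m)
    if missing.any():
        warnings.warn(f"shelf_partition: {int(missing.sum())} cells missing depth assigned off-shelf")
    on = (depth_m < threshold) & ~missing
    total = surface.total
    area = surface.grid.cell_area_km2
    out = {}
    for name, mask in (("on_shelf", on), ("off_shelf", ~on)):
        m = float(surface.values[mask].sum())
        a = float(mask.sum() * area)
        out[name] = ZonalSummary(
            zone=name,
            area_km2=a,
            total_mortality=m,
            intensity=m / (a / 1e4) if a > 0 else 0.0,
            percent_of_total=m / total if total > 0 else 0.0,
        )
    return out
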
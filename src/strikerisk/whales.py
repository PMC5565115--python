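"""Whale-side model inputs: density surfaces and dive-depth profiles.

Density (whales/km^2) from an upstream species distribution model is
regridded onto the analysis grid and converted to expected whales per
cell. Archival-tag depth series are drift-corrected, binned into 1-m
time-at-depth, and turned into a cumulative proportion-of-time-above-
depth curve; evaluated at the hull draft this is the probability the
whale occupies the strike zone during an encounter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

from .grid import AnalysisGrid

log = logging.getLogger(__name__)

__all__ = [
    "DensitySurface",
    "DiveProfile",
    "regrid_density",
    "zero_offset_correction",
    "cumulative_depth_profile",
    "strike_zone_probability",
]


@dataclass
class DensitySurface:
    """Per-cell whale density (whales/km^2) and expected abundance."""

    grid: AnalysisGrid
    density: np.ndarray       # whales/km^2, aligned to cell id
    missing: np.ndarray | None = None   # cells outside the source extent

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (self.grid.n_cells,):
            raise ValueError("density must have one value per cell")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    @property
    def abundance(self) -> np.ndarray:
        """Expected whales per cell: density x cell area."""
        return self.density * self.grid.cell_area_km2

    @property
    def total_abundance(self) -> float:
        return float(self.abundance.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": np.arange(self.grid.n_cells),
            "density_per_km2": self.density,
            "abundance": self.abundance,
        })


def regrid_density(source: xr.DataArray, grid: AnalysisGrid) -> DensitySurface:
    """Bilinearly interpolate a gridded density raster onto cell centers.

    ``source`` must carry 1-D ``x``/``y`` coordinates in the same projected
    CRS as the grid (meters). Cells outside the raster extent are flagged
    missing and treated as zero density with a warning.
    """
    xs = source["x"].values
    ys = source["y"].values
    vals = source.transpose("y", "x").values
    interp = RegularGridInterpolator((ys, xs), vals, method="linear",
                                     bounds_error=False, fill_value=np.nan)
    cx, cy = grid.cell_centers()
    out = interp(np.column_stack([cy, cx]))
    missing = np.isnan(out)
    if missing.any():
        log.warning("regrid_density: %d cells outside the raster extent set to zero",
                    int(missing.sum()))
        out = np.where(missing, 0.0, out)
    out = np.maximum(out, 0.0)
    return DensitySurface(grid=grid, density=out, missing=missing)


def zero_offset_correction(
    series: pd.DataFrame,
    window: pd.Timedelta = pd.Timedelta(minutes=30),
    rank: int = 10,
) -> pd.DataFrame:
    """Remove slow pressure-sensor drift from a tag depth series.

    Within each ``window``, the ``rank``-th shallowest reading is taken as
    the surface and subtracted from all depths in the window (using an
    order statistic rather than the minimum avoids recalibrating on errant
    spikes). Corrected depths are clipped at zero. Windows with fewer than
    ``rank`` samples inherit the previous window's offset.

    ``series`` needs ``timestamp`` and ``depth_m`` columns; returns a copy
    with ``depth_m`` corrected and the applied ``offset_m`` recorded.
    """
    if series.empty:
        raise ValueError("empty depth series")
    df = series.sort_values("timestamp").reset_index(drop=True).copy()
    t0 = df["timestamp"].iloc[0]
    win_idx = ((df["timestamp"] - t0) // window).astype(int)
    offsets = np.zeros(len(df))
    prev = 0.0
    for w, idx in df.groupby(win_idx).groups.items():
        depths = df.loc[idx, "depth_m"].to_numpy()
        if len(depths) >= rank:
            prev = float(np.sort(depths)[rank - 1])
        else:
            log.info("zero_offset_correction: window %s has %d < %d samples; carrying offset",
                     w, len(depths), rank)
        offsets[np.asarray(idx)] = prev
    df["offset_m"] = offsets
    df["depth_m"] = np.maximum(df["depth_m"] - offsets, 0.0)
    return df


@dataclass
class DiveProfile:
    """Time-at-depth in 1-m bins with its cumulative-above-depth curve."""

    species_code: str
    bin_edges: np.ndarray       # meters, length n_bins + 1, starting at 0
    time_fraction: np.ndarray   # proportion of time per bin, sums to 1

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.time_fraction = np.asarray(self.time_fraction, dtype=float)
        if np.any(self.time_fraction < 0):
            raise ValueError("time fractions must be non-negative")
        if abs(self.time_fraction.sum() - 1.0) > 1e-9:
            raise ValueError("time fractions must sum to 1")

    @property
    def max_depth(self) -> float:
        return float(self.bin_edges[-1])

    def cumulative_above(self, depth_m) -> np.ndarray | float:
        """Proportion of time spent at or above ``depth_m``.

        Piecewise-linear within bins; 1 beyond the deepest observed depth.
        Non-decreasing in depth.
        """
        depth = np.asarray(depth_m, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(self.time_fraction)])
        out = np.interp(depth, self.bin_edges, cum, left=0.0, right=1.0)
        return float(out) if np.isscalar(depth_m) else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "depth_m": self.bin_edges[1:],
            "time_fraction": self.time_fraction,
            "cumulative_above": self.cumulative_above(self.bin_edges[1:]),
        })


def cumulative_depth_profile(
    corrected: pd.DataFrame,
    species_code: str = "",
    bin_width: float = 1.0,
) -> DiveProfile:
    """Bin a corrected depth series into time-at-depth and its cumulative form."""
    if corrected.empty:
        raise ValueError("empty depth series")
    depths = corrected["depth_m"].to_numpy(dtype=float)
    if np.any(depths < 0):
        raise ValueError("depths must be non-negative (run zero_offset_correction first)")
    n_bins = max(int(np.ceil((depths.max() + 1e-9) / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(depths, bins=edges)
    # samples exactly at the deepest edge land in the last bin via histogram
    return DiveProfile(species_code=species_code, bin_edges=edges,
                       time_fraction=counts / counts.sum())


def strike_zone_probability(
    profile: DiveProfile,
    mean_draft: float,
    multiplier: float = 1.0,
) -> float:
    """P(whale within the strike zone) = time above multiplier x draft.

    The strike zone is the hull-swept upper layer: the mean vessel draft,
    optionally extended by 1.5x or 2x. Depths at the boundary count as
    inside. Drafts beyond the deepest dive give probability 1.
    """
    if mean_draft <= 0:
        raise ValueError("mean draft must be positive")
    return float(profile.cumulative_above(multiplier * mean_draft))
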
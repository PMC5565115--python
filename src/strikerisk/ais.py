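"""AIS record processing: filtering, voyage/track building, per-cell stats.

Raw AIS-style point records (one row per transmission) become, per grid
cell and month: kriged mean vessel speed / draft / beam with standard
errors, clipped track length, voyage count, and transit time — the
vessel-side inputs of the strike model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .grid import AnalysisGrid
from .kriging import VariogramSpec, krige_field
from .projection import AlbersEqualArea

log = logging.getLogger(__name__)

KNOT_TO_KMH = 1.852

#: canonical column names used throughout the package
CANONICAL_COLUMNS = [
    "vessel_id", "timestamp", "lon", "lat", "sog_kn",
    "draft_m", "beam_m", "vessel_type", "nav_status",
]

#: MarineCadastre-style header mapping (configurable at ingest)
MARINECADASTRE_COLUMN_MAP = {
    "MMSI": "vessel_id",
    "BaseDateTime": "timestamp",
    "LAT": "lat",
    "LON": "lon",
    "SOG": "sog_kn",
    "VesselType": "vessel_type",
    "Draft": "draft_m",
    "Width": "beam_m",
    "Status": "nav_status",
}

ALLOWED_TYPES = frozenset({"cargo", "passenger", "tug"})


def read_ais_csv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read an AIS CSV (gzip accepted), renaming headers to canonical names.

    Rows with unparseable timestamps or coordinates are dropped and counted.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    elif set(MARINECADASTRE_COLUMN_MAP) & set(df.columns):
        df = df.rename(columns=MARINECADASTRE_COLUMN_MAP)
    n0 = len(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce")
    for col in ("lon", "lat", "sog_kn", "draft_m", "beam_m"):
        if col in df:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=["timestamp", "lon", "lat"])
    df = df[(df["lat"].between(-90, 90)) & (df["lon"].between(-180, 180))]
    dropped = n0 - len(df)
    if dropped:
        log.warning("read_ais_csv: dropped %d unparseable rows", dropped)
    return df.reset_index(drop=True)


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    removed_slow: int = 0
    removed_shallow_draft: int = 0
    removed_type: int = 0
    removed_not_underway: int = 0


def filter_records(
    records: pd.DataFrame,
    min_speed: float = 1.0,
    min_draft: float = 1.0,
    allowed_types: frozenset[str] = ALLOWED_TYPES,
) -> pd.DataFrame:
    """Keep underway cargo/passenger/tug records faster than ``min_speed``
    knots with draft of at least ``min_draft`` meters.

    A per-rule removal count is logged and attached as
    ``df.attrs['filter_report']``. Idempotent.
    """
    rep = FilterReport(n_input=len(records))
    ok_type = records["vessel_type"].isin(allowed_types)
    ok_underway = records["nav_status"].eq("underway") if "nav_status" in records else pd.Series(True, index=records.index)
    ok_speed = records["sog_kn"] > min_speed
    ok_draft = records["draft_m"] >= min_draft
    rep.removed_type = int((~ok_type).sum())
    rep.removed_not_underway = int((ok_type & ~ok_underway).sum())
    rep.removed_slow = int((ok_type & ok_underway & ~ok_speed).sum())
    rep.removed_shallow_draft = int((ok_type & ok_underway & ok_speed & ~ok_draft).sum())
    out = records[ok_type & ok_underway & ok_speed & ok_draft].reset_index(drop=True)
    rep.n_kept = len(out)
    log.info("filter_records: %s", rep)
    if rep.n_kept == 0:
        log.warning("filter_records: no surviving records; downstream cells get zero vessel activity")
    out.attrs["filter_report"] = rep
    return out


@dataclass
class Track:
    """One voyage of one vessel: projected polyline with per-vertex data."""

    vessel_id: str
    voyage_id: str
    xy: np.ndarray                  # (n, 2) projected meters
    times: pd.DatetimeIndex
    speeds_kn: np.ndarray
    draft_m: float
    beam_m: float

    @property
    def geometry(self):
        if len(self.xy) < 2:
            return Point(self.xy[0])
        return LineString(self.xy)

    @property
    def length_km(self) -> float:
        if len(self.xy) < 2:
            return 0.0
        return float(LineString(self.xy).length) / 1000.0


def build_tracks(
    records: pd.DataFrame,
    projection: AlbersEqualArea,
    max_gap: pd.Timedelta = pd.Timedelta(hours=6),
) -> list[Track]:
    """Group records into per-vessel voyages and build projected polylines.

    Records are sorted per vessel by time; a gap longer than ``max_gap``
    starts a new voyage. Single-ping voyages are retained (they count as
    voyages but contribute no track length).
    """
    tracks: list[Track] = []
    for vessel_id, g in records.groupby("vessel_id", sort=True):
        g = g.sort_values("timestamp")
        gaps = g["timestamp"].diff() > max_gap
        for k, (_, seg) in enumerate(g.groupby(gaps.cumsum())):
            x, y = projection.forward(seg["lon"].to_numpy(), seg["lat"].to_numpy())
            tracks.append(
                Track(
                    vessel_id=str(vessel_id),
                    voyage_id=f"{vessel_id}/{k}",
                    xy=np.column_stack([x, y]),
                    times=pd.DatetimeIndex(seg["timestamp"]),
                    speeds_kn=seg["sog_kn"].to_numpy(dtype=float),
                    draft_m=float(seg["draft_m"].iloc[0]),
                    beam_m=float(seg["beam_m"].iloc[0]),
                )
            )
    return tracks


def cell_track_stats(tracks: list[Track], grid: AnalysisGrid) -> pd.DataFrame:
    """Clip tracks to grid cells: per-cell track length (km) and voyage count.

    Length is conserved under clipping; a voyage is counted once per cell
    whose interior its polyline intersects.
    """
    length = np.zeros(grid.n_cells)
    voyages: list[set[str]] = [set() for _ in range(grid.n_cells)]
    for tr in tracks:
        if len(tr.xy) < 2:
            cid = int(grid.locate(tr.xy[0, 0], tr.xy[0, 1]))
            if cid >= 0:
                voyages[cid].add(tr.voyage_id)
            continue
        line = LineString(tr.xy)
        minx, miny, maxx, maxy = line.bounds
        c0 = max(int((minx - grid.x0) // grid.cell_size), 0)
        c1 = min(int((maxx - grid.x0) // grid.cell_size), grid.nx - 1)
        r0 = max(int((miny - grid.y0) // grid.cell_size), 0)
        r1 = min(int((maxy - grid.y0) // grid.cell_size), grid.ny - 1)
        for row in range(r0, r1 + 1):
            for col in range(c0, c1 + 1):
                cid = row * grid.nx + col
                inter = line.intersection(grid.cell_polygon(cid))
                if inter.is_empty:
                    continue
                if inter.length > 0:
                    length[cid] += inter.length / 1000.0
                    voyages[cid].add(tr.voyage_id)
    return pd.DataFrame(
        {
            "cell_id": np.arange(grid.n_cells),
            "track_length_km": length,
            "n_voyages": [len(v) for v in voyages],
        }
    ).set_index("cell_id")


def transit_time(
    track_length_km: float,
    mean_speed_kn: float,
    n_voyages: int,
    convention: str = "per_vessel",
) -> float:
    """Vessel transit time (hours) in a cell.

    ``per_vessel``: mean time per voyage, (length/speed) / n_voyages, so
    that t * N_b recovers total fleet time in the mortality product.
    ``total``: the literal fleet reading, (length/speed) * n_voyages.
    """
    if mean_speed_kn <= 0:
        raise ValueError("mean speed must be positive")
    if track_length_km == 0 or n_voyages == 0:
        return 0.0
    base = track_length_km / (mean_speed_kn * KNOT_TO_KMH)
    if convention == "per_vessel":
        return base / n_voyages
    if convention == "total":
        return base * n_voyages
    raise ValueError(f"unknown transit-time convention: {convention!r}")


def vessel_cell_stats(
    records: pd.DataFrame,
    tracks: list[Track],
    grid: AnalysisGrid,
    projection: AlbersEqualArea,
    variogram: VariogramSpec | None = None,
    time_convention: str = "per_vessel",
) -> pd.DataFrame:
    """Assemble per-cell vessel statistics (VesselCellStats).

    Kriges speed/draft/beam point reports onto cell centers and joins
    clipped track length, voyage count and transit time.
    """
    stats = cell_track_stats(tracks, grid)
    cx, cy = grid.cell_centers()
    targets = np.column_stack([cx, cy])
    x, y = projection.forward(records["lon"].to_numpy(), records["lat"].to_numpy())
    xy = np.column_stack([x, y])
    for col, out_name in (("sog_kn", "speed"), ("draft_m", "draft"), ("beam_m", "width")):
        res = krige_field(xy, records[col].to_numpy(dtype=float), targets, spec=variogram)
        stats[f"mean_{out_name}"] = res.predicted
        stats[f"{out_name}_error"] = res.std_error
    stats["transit_time_h"] = [
        transit_time(row.track_length_km, row.mean_speed, int(row.n_voyages), time_convention)
        if row.n_voyages > 0 and row.mean_speed > 0
        else 0.0
        for row in stats.itertuples()
    ]
    return stats
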
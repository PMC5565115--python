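"""Seeded generators for every input the pipeline consumes.

The default scenario emulates the statistical structure of the real
inputs: vessels transiting fixed lanes at 8–25 kn with 5–18 m drafts and
a fixed AIS reporting interval, coastally concentrated Gaussian whale-
density hotspots, dive series alternating surfacings with deep foraging
dives (plus slow sensor drift so the zero-offset correction has work to
do), Poisson stranding records with keyword-bearing narratives, and
simple rectangular jurisdictions. Every generator is a pure function of
(spec, seed): a fixed seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import box

from .grid import AnalysisGrid
from .projection import AlbersEqualArea
from .summaries import Jurisdiction, JurisdictionSet

__all__ = [
    "LaneSpec", "HotspotSpec", "DiveRegime", "StrandingScenario", "ScenarioSpec",
    "synth_ais", "synth_density", "synth_dives", "synth_strandings",
    "synth_jurisdictions", "synth_bathymetry", "default_scenario", "write_fixtures",
]

AIS_REPORT_INTERVAL_S = 300.0  # typical AIS class-A reporting cadence used here


@dataclass(frozen=True)
class LaneSpec:
    """A shipping lane: straight segment in projected meters."""

    name: str
    start_xy: tuple[float, float]
    end_xy: tuple[float, float]
    voyages_per_month: int = 20
    speed_mean_kn: float = 14.0
    speed_sd_kn: float = 2.5
    draft_mean_m: float = 11.0
    draft_sd_m: float = 2.5
    width_mean_m: float = 30.0
    width_sd_m: float = 5.0
    vessel_type: str = "cargo"
    lateral_sd_m: float = 1500.0


@dataclass(frozen=True)
class HotspotSpec:
    """Gaussian whale-density hotspot: total mass in whales."""

    center_xy: tuple[float, float]
    sd_m: float
    total_whales: float


@dataclass(frozen=True)
class DiveRegime:
    """Alternating surfacing/foraging-dive cycle for one species."""

    surface_fraction: float = 0.35
    dive_duration_s: float = 600.0
    dive_depth_mean_m: float = 150.0
    dive_depth_sd_m: float = 40.0
    surface_depth_sd_m: float = 0.4
    drift_m_per_hour: float = 1.5     # sensor drift the correction must remove
    sample_interval_s: float = 5.0
    total_hours: float = 24.0


@dataclass(frozen=True)
class StrandingScenario:
    annual_rates: dict = field(default_factory=lambda: {"blue": 1.0, "humpback": 1.4, "fin": 1.1})
    bow_fraction: float = 0.15
    port_fraction: float = 0.1
    n_years: int = 10
    lat_range: tuple[float, float] = (32.0, 47.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """Full synthetic study: grid, traffic, whales, dives, strandings."""

    seed: int = 0
    grid_x0: float = 0.0
    grid_y0: float = 0.0
    grid_nx: int = 10
    grid_ny: int = 10
    cell_size_m: float = 12_000.0
    months: tuple[int, ...] = (6, 7, 8, 9, 10, 12)
    year: int = 2014
    lanes: tuple[LaneSpec, ...] = ()
    hotspots: dict = field(default_factory=dict)        # species -> tuple[HotspotSpec]
    dive_regimes: dict = field(default_factory=dict)    # species -> DiveRegime
    strandings: StrandingScenario = field(default_factory=StrandingScenario)
    slow_ping_rate: float = 0.0
    shallow_draft_voyage_rate: float = 0.0
    bad_type_voyage_rate: float = 0.0

    def grid(self) -> AnalysisGrid:
        return AnalysisGrid(self.grid_x0, self.grid_y0, self.grid_nx,
                            self.grid_ny, self.cell_size_m)

    def projection(self) -> AlbersEqualArea:
        return AlbersEqualArea()


def _rng(spec: ScenarioSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng((spec.seed, salt))


def _species_salt(species: str) -> int:
    # stable across processes (unlike built-in str hash)
    return zlib.crc32(species.encode()) % 10_000


def synth_ais(spec: ScenarioSpec) -> pd.DataFrame:
    """AIS point records for every lane voyage, 5-minute reporting interval.

    Vessel draft/beam are constant within a voyage; per-ping speed jitters
    around the voyage speed. Planted filter violations (slow pings,
    sub-1-m drafts, disallowed vessel types) are emitted at the configured
    rates and labeled in a ``planted`` column ('' for clean records).
    """
    if not spec.lanes:
        raise ValueError("scenario must define at least one lane")
    rng = _rng(spec, 1)
    proj = spec.projection()
    rows = []
    vessel_counter = 0
    for lane in spec.lanes:
        p0 = np.array(lane.start_xy)
        p1 = np.array(lane.end_xy)
        seg = p1 - p0
        seg_len = float(np.hypot(*seg))
        u = seg / seg_len
        normal = np.array([-u[1], u[0]])
        for month in spec.months:
            for _ in range(lane.voyages_per_month):
                vessel_counter += 1
                vessel_id = 100_000_000 + vessel_counter
                speed_kn = float(np.clip(rng.normal(lane.speed_mean_kn, lane.speed_sd_kn), 8.0, 25.0))
                draft = float(np.clip(rng.normal(lane.draft_mean_m, lane.draft_sd_m), 5.0, 18.0))
                beam = float(np.clip(rng.normal(lane.width_mean_m, lane.width_sd_m), 15.0, 50.0))
                vtype = lane.vessel_type
                planted_voyage = ""
                if rng.random() < spec.shallow_draft_voyage_rate:
                    draft = float(rng.uniform(0.2, 0.9))
                    planted_voyage = "shallow"
                elif rng.random() < spec.bad_type_voyage_rate:
                    vtype = "fishing"
                    planted_voyage = "type"
                forward = rng.random() < 0.5
                a, b = (p0, p1) if forward else (p1, p0)
                direction = (b - a) / seg_len
                offset = rng.normal(0.0, lane.lateral_sd_m)
                v_ms = speed_kn * 0.514444
                n_pings = int(seg_len / (v_ms * AIS_REPORT_INTERVAL_S)) + 1
                day = rng.integers(1, 28)
                t0 = pd.Timestamp(year=spec.year, month=month, day=int(day)) + pd.Timedelta(
                    seconds=float(rng.uniform(0, 86_400)))
                k = np.arange(n_pings)
                pos = a[None, :] + direction[None, :] * (v_ms * AIS_REPORT_INTERVAL_S) * k[:, None] \
                    + normal[None, :] * offset
                sog = np.maximum(speed_kn + rng.normal(0.0, 0.3, size=n_pings), 1.2)
                planted = np.full(n_pings, planted_voyage, dtype=object)
                if not planted_voyage and spec.slow_ping_rate > 0:
                    slow = rng.random(n_pings) < spec.slow_ping_rate
                    sog[slow] = rng.uniform(0.1, 0.9, size=int(slow.sum()))
                    planted[slow] = "slow"
                lon, lat = proj.inverse(pos[:, 0], pos[:, 1])
                rows.append(pd.DataFrame({
                    "vessel_id": vessel_id,
                    "timestamp": t0 + pd.to_timedelta(AIS_REPORT_INTERVAL_S * k, unit="s"),
                    "lon": lon, "lat": lat, "sog_kn": np.round(sog, 2),
                    "draft_m": draft, "beam_m": beam, "vessel_type": vtype,
                    "nav_status": "underway", "planted": planted,
                }))
    df = pd.concat(rows, ignore_index=True)
    return df.sort_values(["vessel_id", "timestamp"]).reset_index(drop=True)


def synth_density(spec: ScenarioSpec, species: str, resolution_m: float = 3_000.0) -> xr.DataArray:
    """Sum-of-Gaussians density raster (whales/km^2) on a fine grid.

    Hotspot centers are jittered by the seed (different seeds move the
    hotspots but conserve the total mass each contributes).
    """
    hotspots = spec.hotspots.get(species)
    if not hotspots:
        raise ValueError(f"scenario defines no hotspots for species {species!r}")
    rng = _rng(spec, 20_000 + _species_salt(species))
    g = spec.grid()
    x0, y0, x1, y1 = g.bounds
    # margin wide enough that each kernel's mass is captured (>=3 sd)
    margin = max(2 * resolution_m, 3.0 * max(h.sd_m for h in hotspots))
    xs = np.arange(x0 - margin, x1 + margin + resolution_m, resolution_m)
    ys = np.arange(y0 - margin, y1 + margin + resolution_m, resolution_m)
    xx, yy = np.meshgrid(xs, ys)
    dens = np.zeros_like(xx)
    for h in hotspots:
        cx = h.center_xy[0] + rng.normal(0.0, 0.2 * h.sd_m)
        cy = h.center_xy[1] + rng.normal(0.0, 0.2 * h.sd_m)
        # bivariate normal kernel; mass in whales, distances in meters,
        # density expressed per km^2 (1e6 m^2)
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        dens += h.total_whales / (2 * np.pi * h.sd_m**2) * np.exp(-0.5 * r2 / h.sd_m**2) * 1e6
    return xr.DataArray(dens, coords={"y": ys, "x": xs}, dims=("y", "x"), name="density_per_km2")


@dataclass
class SynthDiveSeries:
    """Generated tag series plus drift-free ground truth."""

    series: pd.DataFrame        # timestamp, depth_m (with drift applied)
    true_depths: np.ndarray     # drift-free depths, same order

    def true_fraction_above(self, depth_m: float) -> float:
        return float(np.mean(self.true_depths <= depth_m))


def synth_dives(spec: ScenarioSpec, species: str) -> SynthDiveSeries:
    """Depth time series alternating surfacings and square foraging dives.

    A linear sensor drift is injected so that ``zero_offset_correction``
    is exercised; the drift-free series is returned as ground truth.
    """
    regime = spec.dive_regimes.get(species)
    if regime is None:
        raise ValueError(f"scenario defines no dive regime for species {species!r}")
    rng = _rng(spec, 30_000 + _species_salt(species))
    sf = regime.surface_fraction
    if not 0.0 < sf < 1.0:
        raise ValueError("surface fraction must lie in (0, 1)")
    surface_duration = regime.dive_duration_s * sf / (1.0 - sf)
    n = int(regime.total_hours * 3600.0 / regime.sample_interval_s)
    depths = np.empty(n)
    i = 0
    at_surface = True

    def duration(mean_s):
        # truncated normal: foraging-cycle durations are regular, not heavy-tailed
        return float(np.clip(rng.normal(mean_s, 0.25 * mean_s), 0.5 * mean_s, 1.5 * mean_s))

    while i < n:
        if at_surface:
            dur = max(duration(surface_duration), 2 * regime.sample_interval_s)
            k = min(int(dur / regime.sample_interval_s), n - i)
            depths[i:i + k] = np.abs(rng.normal(0.3, regime.surface_depth_sd_m, size=k))
        else:
            dur = max(duration(regime.dive_duration_s), 2 * regime.sample_interval_s)
            k = min(int(dur / regime.sample_interval_s), n - i)
            d = max(rng.normal(regime.dive_depth_mean_m, regime.dive_depth_sd_m), 5.0)
            depths[i:i + k] = d + rng.normal(0.0, 1.0, size=k)
        i += k
        at_surface = not at_surface
    t = pd.Timestamp(year=spec.year, month=6, day=1) + pd.to_timedelta(
        np.arange(n) * regime.sample_interval_s, unit="s")
    drift = regime.drift_m_per_hour * (np.arange(n) * regime.sample_interval_s / 3600.0)
    series = pd.DataFrame({"timestamp": t, "depth_m": depths + drift})
    return SynthDiveSeries(series=series, true_depths=depths)


def synth_strandings(spec: ScenarioSpec) -> pd.DataFrame:
    """Poisson stranding records with keyword-bearing narratives."""
    sc = spec.strandings
    rng = _rng(spec, 4)
    rows = []
    rec = 0
    for species, rate in sorted(sc.annual_rates.items()):
        if rate < 0:
            raise ValueError("stranding rates must be non-negative")
        for year_off in range(sc.n_years):
            for _ in range(rng.poisson(rate)):
                rec += 1
                lat = float(rng.uniform(*sc.lat_range))
                lon = float(rng.uniform(-126.0, -117.0))
                narrative = "carcass reported stranded on beach"
                if rng.random() < sc.bow_fraction:
                    narrative = "carcass found on the bow of an arriving vessel"
                elif rng.random() < sc.port_fraction:
                    narrative = "carcass discovered floating in the inner harbor"
                date = pd.Timestamp(year=2006 + year_off, month=int(rng.integers(1, 13)),
                                    day=int(rng.integers(1, 28)))
                rows.append((f"SR{rec:04d}", species, date.date().isoformat(), lat, lon, narrative))
    return pd.DataFrame(rows, columns=["record_id", "species", "date", "lat", "lon", "narrative"])


def synth_jurisdictions(spec: ScenarioSpec) -> JurisdictionSet:
    """Simple rectangular jurisdictions over the grid (projected CRS)."""
    x0, y0, x1, y1 = spec.grid().bounds
    w, h = x1 - x0, y1 - y0
    zones = [
        Jurisdiction("coastal_band", "state_waters", box(x1 - 0.15 * w, y0, x1, y1)),
        Jurisdiction("lane_corridor", "TSS", box(x0, y0 + 0.45 * h, x1, y0 + 0.55 * h)),
        Jurisdiction("sanctuary", "NMS", box(x0 + 0.2 * w, y0 + 0.55 * h, x0 + 0.6 * w, y1)),
        Jurisdiction("feeding_bia", "BIA", box(x1 - 0.4 * w, y0, x1, y0 + 0.4 * h)),
    ]
    return JurisdictionSet(zones)


def synth_bathymetry(spec: ScenarioSpec) -> np.ndarray:
    """Per-cell water depth: shallow shelf at the eastern (coastal) edge,
    deepening linearly offshore to the west."""
    g = spec.grid()
    cx, _ = g.cell_centers()
    x0, _, x1, _ = g.bounds
    frac_offshore = (x1 - cx) / (x1 - x0)
    return 30.0 + frac_offshore * 2970.0


def default_scenario(seed: int = 0) -> ScenarioSpec:
    """The package's reference study: a 120 km x 120 km coastal region,
    two lanes (a north–south coastwise corridor and a port approach),
    coastally concentrated hotspots and species-typical dive regimes."""
    side = 120_000.0
    lanes = (
        LaneSpec("coastwise", start_xy=(66_000.0, 0.0), end_xy=(66_000.0, side),
                 voyages_per_month=18, speed_mean_kn=14.0, draft_mean_m=11.0),
        LaneSpec("port_approach", start_xy=(0.0, 54_000.0), end_xy=(side, 66_000.0),
                 voyages_per_month=12, speed_mean_kn=16.0, draft_mean_m=12.5),
    )
    hotspots = {
        "blue": (HotspotSpec((90_000.0, 36_000.0), 18_000.0, 40.0),
                 HotspotSpec((60_000.0, 84_000.0), 25_000.0, 25.0)),
        "humpback": (HotspotSpec((100_000.0, 66_000.0), 14_000.0, 55.0),),
        "fin": (HotspotSpec((40_000.0, 60_000.0), 30_000.0, 50.0),),
    }
    dive_regimes = {
        "blue": DiveRegime(surface_fraction=0.33, dive_depth_mean_m=160.0),
        "humpback": DiveRegime(surface_fraction=0.45, dive_depth_mean_m=80.0,
                               dive_depth_sd_m=25.0),
        "fin": DiveRegime(surface_fraction=0.38, dive_depth_mean_m=140.0),
    }
    return ScenarioSpec(seed=seed, lanes=lanes, hotspots=hotspots,
                        dive_regimes=dive_regimes,
                        slow_ping_rate=0.02, shallow_draft_voyage_rate=0.03,
                        bad_type_voyage_rate=0.03)


def write_fixtures(spec: ScenarioSpec, out_dir, species=("blue", "humpback", "fin")) -> dict:
    """Materialize a scenario to disk in the formats the ingest code reads.

    Returns a manifest of the written paths.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proj = spec.projection()
    manifest = {}

    ais = synth_ais(spec).drop(columns=["planted"])
    ais = ais.rename(columns={
        "vessel_id": "MMSI", "timestamp": "BaseDateTime", "lat": "LAT", "lon": "LON",
        "sog_kn": "SOG", "vessel_type": "VesselType", "draft_m": "Draft",
        "beam_m": "Width", "nav_status": "Status",
    })
    p = out / "ais.csv"
    ais.to_csv(p, index=False)
    manifest["ais"] = str(p)

    for sp in species:
        raster = synth_density(spec, sp)
        xx, yy = np.meshgrid(raster["x"].values, raster["y"].values)
        lon, lat = proj.inverse(xx.ravel(), yy.ravel())
        df = pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(), "lon": lon, "lat": lat,
                           "density_per_km2": raster.values.ravel()})
        p = out / f"density_{sp}.csv"
        df.to_csv(p, index=False)
        manifest[f"density_{sp}"] = str(p)

        dives = synth_dives(spec, sp)
        p = out / f"dives_{sp}.csv"
        dives.series.to_csv(p, index=False)
        manifest[f"dives_{sp}"] = str(p)

    p = out / "strandings.csv"
    synth_strandings(spec).to_csv(p, index=False)
    manifest["strandings"] = str(p)

    p = out / "jurisdictions.geojson"
    with open(p, "w") as fh:
        json.dump(synth_jurisdictions(spec).to_geojson(), fh)
    manifest["jurisdictions"] = str(p)

    depth = synth_bathymetry(spec)
    p = out / "bathymetry.csv"
    pd.DataFrame({"cell_id": np.arange(len(depth)), "depth_m": depth}).to_csv(p, index=False)
    manifest["bathymetry"] = str(p)

    p = out / "grid.geojson"
    spec.grid().write_geojson(p)
    manifest["grid"] = str(p)
    return manifest
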
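"""Orchestration: config -> ingest -> per-cell inputs -> monthly mortality
under the three avoidance scenarios -> summaries and reports.

The heavy lifting lives in the other modules; this one wires them
together, vectorizes the per-cell mortality product over the grid, and
mirrors the shape of the published summary tables (study-area totals per
species x avoidance model, percentile concentration statistics, zonal
statistics, PBR ratios).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import ais as ais_mod
from .core import (AvoidanceModel, LethalityModel, MortalitySurface, SpeciesParams,
                   aggregate_mortality, load_species_defaults)
from .grid import AnalysisGrid
from .kriging import VariogramSpec
from .projection import AlbersEqualArea
from .strandings import extrapolation_report, latitudinal_bins, transport_flags
from .summaries import JurisdictionSet, pbr_comparison, shelf_partition, threshold_mask, zonal_summary
from .units import HOUR_S, KNOT_TO_MS
from .whales import (DensitySurface, DiveProfile, cumulative_depth_profile,
                     regrid_density, strike_zone_probability, zero_offset_correction)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_model", "sensitivity_suite",
           "prepare_inputs", "compute_surfaces", "DEFAULT_AVOIDANCE_MODELS"]

DEFAULT_AVOIDANCE_MODELS = {
    "model1": AvoidanceModel(variant="speed_logistic"),
    "model2": AvoidanceModel(variant="constant"),
    "model3": AvoidanceModel(variant="none"),
}


@dataclass
class RunConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    ais_csv: str = ""
    density_csvs: dict = field(default_factory=dict)     # species -> path
    dive_csvs: dict = field(default_factory=dict)        # species -> path
    strandings_csv: str = ""
    jurisdictions_geojson: str = ""
    bathymetry_csv: str = ""
    grid_x0: float = 0.0
    grid_y0: float = 0.0
    grid_nx: int = 10
    grid_ny: int = 10
    cell_size_m: float = 12_000.0
    months: tuple = (6, 7, 8, 9, 10, 12)
    species: tuple = ("blue", "humpback", "fin")
    avoidance: dict = field(default_factory=lambda: {
        k: dataclasses.asdict(v) for k, v in DEFAULT_AVOIDANCE_MODELS.items()})
    lethality_intercept: float = LethalityModel().intercept
    lethality_slope: float = LethalityModel().slope_per_knot
    r_c_variant: str = "literal"
    time_convention: str = "per_vessel"
    strike_zone_multiplier: float = 1.0
    swim_speed_variant: str = "mean"
    max_track_gap_hours: float = 6.0
    seed: int = 0
    output_dir: str = "strikerisk_out"

    def grid(self) -> AnalysisGrid:
        return AnalysisGrid(self.grid_x0, self.grid_y0, self.grid_nx,
                            self.grid_ny, self.cell_size_m)

    def avoidance_models(self) -> dict[str, AvoidanceModel]:
        return {k: AvoidanceModel(**v) for k, v in self.avoidance.items()}

    def lethality_model(self) -> LethalityModel:
        return LethalityModel(self.lethality_intercept, self.lethality_slope)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["months"] = list(self.months)
        d["species"] = list(self.species)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["months"] = tuple(d.get("months", ()))
        d["species"] = tuple(d.get("species", ()))
        return cls(**d)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["months"] = list(self.months)
        d["species"] = list(self.species)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ProcessedInputs:
    """Ingested, per-cell model inputs shared by all model variants."""

    grid: AnalysisGrid
    monthly_vessel_stats: dict            # month -> DataFrame (VesselCellStats)
    density: dict                         # species -> DensitySurface
    profiles: dict                        # species -> DiveProfile
    jurisdictions: JurisdictionSet | None = None
    bathymetry: np.ndarray | None = None
    report: dict = field(default_factory=dict)


def read_density_csv(path, grid: AnalysisGrid) -> DensitySurface:
    """Long-format gridded density CSV -> DensitySurface.

    Expects projected ``x``/``y`` columns on a regular grid (the format
    the fixture writer emits) plus ``density_per_km2``.
    """
    df = pd.read_csv(path)
    xs = np.sort(df["x"].unique())
    ys = np.sort(df["y"].unique())
    pivot = df.pivot_table(index="y", columns="x", values="density_per_km2")
    da = xr.DataArray(pivot.to_numpy(), coords={"y": ys, "x": xs}, dims=("y", "x"))
    return regrid_density(da, grid)


def read_dive_profile(path, species: str) -> DiveProfile:
    """Dive CSV -> DiveProfile.

    Accepts either a raw series (timestamp, depth_m) — which is
    drift-corrected then binned — or a pre-binned table
    (depth_bin_m, proportion).
    """
    df = pd.read_csv(path)
    if "depth_bin_m" in df.columns:
        fracs = df.sort_values("depth_bin_m")["proportion"].to_numpy(dtype=float)
        edges = np.arange(len(fracs) + 1, dtype=float)
        from .whales import DiveProfile as _DP
        return _DP(species_code=species, bin_edges=edges, time_fraction=fracs / fracs.sum())
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    corrected = zero_offset_correction(df)
    return cumulative_depth_profile(corrected, species_code=species)


def prepare_inputs(config: RunConfig) -> ProcessedInputs:
    """Ingest all files and build the shared per-cell inputs."""
    grid = config.grid()
    proj = AlbersEqualArea()
    report: dict = {"config_hash": config.config_hash()}

    for name in ("ais_csv", "strandings_csv"):
        p = getattr(config, name)
        if p and not Path(p).exists():
            raise FileNotFoundError(f"{name}: {p}")

    records = ais_mod.read_ais_csv(config.ais_csv)
    filtered = ais_mod.filter_records(records)
    report["ais_filter"] = dataclasses.asdict(filtered.attrs["filter_report"]) \
        if hasattr(filtered.attrs.get("filter_report"), "__dataclass_fields__") \
        else str(filtered.attrs.get("filter_report"))
    if filtered.empty:
        log.warning("no AIS records survive filtering: mortality surfaces will be zero")

    monthly = {}
    max_gap = pd.Timedelta(hours=config.max_track_gap_hours)
    for month in config.months:
        sub = filtered[filtered["timestamp"].dt.month == month]
        if sub.empty:
            monthly[month] = None
            continue
        tracks = ais_mod.build_tracks(sub, proj, max_gap=max_gap)
        monthly[month] = ais_mod.vessel_cell_stats(
            sub, tracks, grid, proj, time_convention=config.time_convention)

    density = {sp: read_density_csv(config.density_csvs[sp], grid) for sp in config.species}
    profiles = {sp: read_dive_profile(config.dive_csvs[sp], sp) for sp in config.species}

    jurisdictions = None
    if config.jurisdictions_geojson:
        jurisdictions = JurisdictionSet.from_geojson(config.jurisdictions_geojson)
    bathy = None
    if config.bathymetry_csv:
        bdf = pd.read_csv(config.bathymetry_csv).set_index("cell_id").sort_index()
        bathy = bdf["depth_m"].reindex(np.arange(grid.n_cells)).to_numpy()
    return ProcessedInputs(grid=grid, monthly_vessel_stats=monthly, density=density,
                           profiles=profiles, jurisdictions=jurisdictions,
                           bathymetry=bathy, report=report)


def _avoidance_vec(model: AvoidanceModel, speed_kn: np.ndarray) -> np.ndarray:
    if model.variant == "none":
        return np.zeros_like(speed_kn)
    if model.variant == "constant":
        return np.full_like(speed_kn, model.constant_p)
    z = model.slope * (speed_kn - model.inflection_speed)
    return model.a_max / (1.0 + np.exp(z))


def monthly_mortality(
    stats: pd.DataFrame,
    grid: AnalysisGrid,
    density: DensitySurface,
    profile: DiveProfile,
    species: SpeciesParams,
    avoidance: AvoidanceModel,
    lethality: LethalityModel,
    r_c_variant: str = "literal",
    time_convention: str = "per_vessel",
    strike_zone_multiplier: float = 1.0,
    swim_speed_variant: str = "mean",
) -> MortalitySurface:
    """Vectorized per-cell mortality for one month.

    Identical, cell by cell, to ``core.cell_mortality`` (asserted by the
    test suite); vectorization is purely a speed concern.
    """
    width = stats["mean_width"].to_numpy(dtype=float)
    speed_kn = stats["mean_speed"].to_numpy(dtype=float)
    draft = stats["mean_draft"].to_numpy(dtype=float)
    t_s = stats["transit_time_h"].to_numpy(dtype=float) * HOUR_S
    n_b = stats["n_voyages"].to_numpy(dtype=float)

    body = species.total_length * species.head_width / np.pi
    r_c = width + (body if r_c_variant == "literal" else np.sqrt(body))
    v_m = species.swim_speed(swim_speed_variant)
    v_b = speed_kn * KNOT_TO_MS
    from scipy.special import ellipe
    s = v_m + v_b
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(s > 0, 4.0 * v_m * v_b / np.maximum(s, 1e-300) ** 2, 0.0)
    rel_speed = (2.0 / np.pi) * s * ellipe(m)
    lam = 2.0 * r_c * rel_speed / grid.cell_area_m2

    p_depth = profile.cumulative_above(strike_zone_multiplier * draft)
    p_avoid = _avoidance_vec(avoidance, speed_kn)
    z = lethality.intercept + lethality.slope_per_knot * speed_kn
    p_lethal = 1.0 / (1.0 + np.exp(-z))

    boats = n_b if time_convention == "per_vessel" else 1.0
    deaths = lam * t_s * p_depth * (1.0 - p_avoid) * p_lethal * density.abundance * boats
    deaths = np.where(n_b > 0, deaths, 0.0)
    return MortalitySurface(grid=grid, values=deaths,
                            label=f"{species.species_code}/{avoidance.variant}")


@dataclass
class RunResult:
    surfaces: dict                 # (species, model_name) -> MortalitySurface
    totals: pd.DataFrame           # species x model totals + PBR ratios
    percentile_stats: pd.DataFrame
    zonal: pd.DataFrame | None
    shelf: pd.DataFrame | None
    report: dict

    def surface(self, species: str, model: str = "model2") -> MortalitySurface:
        return self.surfaces[(species, model)]


def compute_surfaces(
    inputs: ProcessedInputs,
    config: RunConfig,
    species_params: dict[str, SpeciesParams] | None = None,
) -> RunResult:
    """Run the mortality model for every species x avoidance model."""
    species_params = species_params or load_species_defaults()
    avoidance_models = config.avoidance_models()
    lethality = config.lethality_model()
    grid = inputs.grid

    surfaces = {}
    for sp in config.species:
        params = species_params[sp]
        for mname, amodel in avoidance_models.items():
            per_month = []
            for month, stats in inputs.monthly_vessel_stats.items():
                if stats is None:
                    per_month.append(MortalitySurface(grid, np.zeros(grid.n_cells)))
                    continue
                per_month.append(monthly_mortality(
                    stats, grid, inputs.density[sp], inputs.profiles[sp], params,
                    amodel, lethality,
                    r_c_variant=config.r_c_variant,
                    time_convention=config.time_convention,
                    strike_zone_multiplier=config.strike_zone_multiplier,
                    swim_speed_variant=config.swim_speed_variant,
                ))
            surfaces[(sp, mname)] = aggregate_mortality(per_month, label=f"{sp}/{mname}")

    total_rows = []
    for sp in config.species:
        for mname in avoidance_models:
            tot = surfaces[(sp, mname)].total
            total_rows.append({
                "species": sp, "model": mname, "total_mortality": tot,
                "pbr": species_params[sp].pbr,
                "pbr_ratio": pbr_comparison(tot, species_params[sp]),
            })
    totals = pd.DataFrame(total_rows)

    pct_rows = []
    for sp in config.species:
        surf = surfaces[(sp, "model2")]
        above_mean = threshold_mask(surf, "above_mean")
        above_p90 = threshold_mask(surf, "above_p90")
        pct_rows.append({
            "species": sp,
            "total_mortality": surf.total,
            "above_mean_mortality": above_mean["mortality_sum"],
            "above_mean_percent": above_mean["percent_of_total"],
            "above_p90_mortality": above_p90["mortality_sum"],
            "above_p90_percent": above_p90["percent_of_total"],
            "above_p90_area_km2": above_p90["area_km2"],
        })
    percentile_stats = pd.DataFrame(pct_rows)

    zonal = None
    if inputs.jurisdictions is not None:
        zrows = []
        for sp in config.species:
            for zs in zonal_summary(surfaces[(sp, "model2")], inputs.jurisdictions):
                zrows.append({"species": sp, **dataclasses.asdict(zs)})
        zonal = pd.DataFrame(zrows)

    shelf = None
    if inputs.bathymetry is not None:
        srows = []
        for sp in config.species:
            parts = shelf_partition(surfaces[(sp, "model2")], inputs.bathymetry)
            for name, zs in parts.items():
                srows.append({"species": sp, "region": name, **dataclasses.asdict(zs)})
        shelf = pd.DataFrame(srows)

    report = dict(inputs.report)
    report.update({
        "r_c_variant": config.r_c_variant,
        "time_convention": config.time_convention,
        "strike_zone_multiplier": config.strike_zone_multiplier,
        "swim_speed_variant": config.swim_speed_variant,
        "lethality": {"intercept": lethality.intercept, "slope_per_knot": lethality.slope_per_knot},
        "avoidance": {k: dataclasses.asdict(v) for k, v in avoidance_models.items()},
        "months": list(config.months),
        "seed": config.seed,
    })
    return RunResult(surfaces=surfaces, totals=totals, percentile_stats=percentile_stats,
                     zonal=zonal, shelf=shelf, report=report)


def run_model(config: RunConfig, write: bool = True) -> RunResult:
    """Full run from a config; optionally writes all outputs to disk."""
    inputs = prepare_inputs(config)
    result = compute_surfaces(inputs, config)

    if config.strandings_csv:
        sdf = pd.read_csv(config.strandings_csv)
        flagged, summary = transport_flags(sdf)
        result.report["stranding_transport"] = summary
        counts = sdf["species"].value_counts().to_dict()
        result.report["stranding_extrapolation"] = extrapolation_report(counts).to_dict("records")
        result.report["stranding_bins"] = latitudinal_bins(sdf).to_dict("records")

    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (sp, mname), surf in result.surfaces.items():
            surf.to_frame().to_csv(out / f"mortality_{sp}_{mname}.csv", index=False)
        result.totals.to_csv(out / "totals.csv", index=False)
        result.percentile_stats.to_csv(out / "percentile_stats.csv", index=False)
        if result.zonal is not None:
            result.zonal.to_csv(out / "zonal.csv", index=False)
        if result.shelf is not None:
            result.shelf.to_csv(out / "shelf.csv", index=False)
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(result.report, fh, indent=2, sort_keys=True, default=str)
    return result


def sensitivity_suite(
    config: RunConfig,
    inputs: ProcessedInputs | None = None,
    swim_variants: tuple = ("mean", "travel", "ars"),
    strike_multipliers: tuple = (1.0, 1.5, 2.0),
) -> pd.DataFrame:
    """Totals and % change vs baseline along the two sensitivity axes.

    The baseline is the config as given (mean swim speed, 1x strike
    zone); each row perturbs exactly one axis.
    """
    inputs = inputs or prepare_inputs(config)
    base = compute_surfaces(inputs, config)
    base_tot = base.totals[base.totals["model"] == "model2"].set_index("species")["total_mortality"]

    rows = []
    for sp in config.species:
        rows.append({"axis": "baseline", "variant": "baseline", "species": sp,
                     "total": base_tot[sp], "delta": 0.0, "delta_pct": 0.0})
    for variant in swim_variants:
        if variant == config.swim_speed_variant:
            continue
        res = compute_surfaces(inputs, replace(config, swim_speed_variant=variant))
        tot = res.totals[res.totals["model"] == "model2"].set_index("species")["total_mortality"]
        for sp in config.species:
            rows.append({"axis": "swim_speed", "variant": variant, "species": sp,
                         "total": tot[sp], "delta": tot[sp] - base_tot[sp],
                         "delta_pct": 100.0 * (tot[sp] / base_tot[sp] - 1.0)})
    for mult in strike_multipliers:
        if mult == config.strike_zone_multiplier:
            continue
        res = compute_surfaces(inputs, replace(config, strike_zone_multiplier=mult))
        tot = res.totals[res.totals["model"] == "model2"].set_index("species")["total_mortality"]
        for sp in config.species:
            rows.append({"axis": "strike_zone", "variant": f"{mult}x", "species": sp,
                         "total": tot[sp], "delta": tot[sp] - base_tot[sp],
                         "delta_pct": 100.0 * (tot[sp] / base_tot[sp] - 1.0)})
    return pd.DataFrame(rows)
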
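"""Encounter-theory strike model.

A ship and a whale are treated as points moving with random independent
headings inside a grid cell of area ``S``. When the pair comes within a
critical radius ``r_c`` an encounter occurs; kinetic (ideal-gas) theory
gives the per-pair encounter rate

    lambda_e = 2 * r_c * E|v_rel| / S,

where ``E|v_rel|`` is the mean relative speed of two headings drawn
uniformly on the circle. An encounter becomes a death only if the whale
occupies the hull's strike zone, fails to avoid the vessel, and the
collision is lethal at the vessel's speed, so the per-cell expectation is

    deaths = lambda_e * t * P(strike depth) * (1 - P(avoid)) * P(lethal | v_b) * N_m * N_b

with ``t`` the vessel transit time, ``N_m`` expected whales and ``N_b``
voyages in the cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import ellipe

from .grid import AnalysisGrid
from .units import KNOT_TO_MS

__all__ = [
    "SpeciesParams",
    "AvoidanceModel",
    "LethalityModel",
    "CellModelInputs",
    "MortalitySurface",
    "load_species_defaults",
    "critical_radius",
    "mean_relative_speed",
    "encounter_rate",
    "avoidance_probability",
    "lethality_probability",
    "cell_mortality",
    "aggregate_mortality",
]

SpeciesCode = Literal["blue", "humpback", "fin"]

#: Speed–lethality logistic transcribed from the empirical East Coast
#: strike-record fit (logit-linear in vessel speed over ground, knots).
DEFAULT_LETHALITY_INTERCEPT = -1.905
DEFAULT_LETHALITY_SLOPE = 0.217


@dataclass(frozen=True)
class SpeciesParams:
    """Morphometrics, swimming speeds and the management removal limit.

    Lengths in meters, speeds in m/s, ``pbr`` in whales/year.
    """

    species_code: str
    total_length: float
    head_width: float
    swim_speed_mean: float
    swim_speed_travel: float
    swim_speed_ars: float
    pbr: float

    def __post_init__(self):
        for name in ("total_length", "head_width", "swim_speed_mean",
                     "swim_speed_travel", "swim_speed_ars", "pbr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def swim_speed(self, variant: str = "mean") -> float:
        return {
            "mean": self.swim_speed_mean,
            "travel": self.swim_speed_travel,
            "ars": self.swim_speed_ars,
        }[variant]


def load_species_defaults() -> dict[str, SpeciesParams]:
    """Packaged default parameter table for blue, humpback and fin whales."""
    with resources.files("strikerisk.data").joinpath("species_defaults.csv").open() as fh:
        df = pd.read_csv(fh)
    out = {}
    for row in df.itertuples(index=False):
        out[row.species_code] = SpeciesParams(
            species_code=row.species_code,
            total_length=row.total_length_m,
            head_width=row.head_width_m,
            swim_speed_mean=row.swim_speed_mean_ms,
            swim_speed_travel=row.swim_speed_travel_ms,
            swim_speed_ars=row.swim_speed_ars_ms,
            pbr=row.pbr,
        )
    return out


@dataclass(frozen=True)
class AvoidanceModel:
    """Whale collision-avoidance scenario.

    ``speed_logistic``: avoidance decays with vessel speed, value
    ``a_max/2`` at the inflection speed (default 11.8 kn, the observed
    change-point in whale–vessel encounter distance).
    ``constant``: fixed probability (default 0.55, the observed rate of
    avoidance-dive initiation). ``none``: zero avoidance.
    """

    variant: Literal["speed_logistic", "constant", "none"] = "constant"
    a_max: float = 0.55
    slope: float = 0.3  # per knot; "low slope"
    inflection_speed: float = 11.8  # knots
    constant_p: float = 0.55

    def __post_init__(self):
        if not (0.0 <= self.a_max <= 1.0 and 0.0 <= self.constant_p <= 1.0):
            raise ValueError("avoidance probabilities must lie in [0, 1]")
        if self.variant == "speed_logistic" and self.slope <= 0:
            raise ValueError("speed_logistic slope must be positive")


@dataclass(frozen=True)
class LethalityModel:
    """Logit-linear probability that a strike kills the whale.

    ``logit P = intercept + slope_per_knot * speed_kn``.
    """

    intercept: float = DEFAULT_LETHALITY_INTERCEPT
    slope_per_knot: float = DEFAULT_LETHALITY_SLOPE

    def __post_init__(self):
        if self.slope_per_knot <= 0:
            raise ValueError("lethality must increase with speed (slope > 0)")


@dataclass(frozen=True)
class CellModelInputs:
    """Per-cell physical inputs to the mortality product (SI units)."""

    area_s: float            # m^2
    vessel_speed: float      # m/s
    vessel_width: float      # m
    vessel_draft: float      # m
    transit_time: float      # s (meaning set by time_convention)
    n_boats: float           # voyages
    n_whales: float          # expected whales
    p_strike_depth: float    # probability

    def __post_init__(self):
        if self.area_s <= 0:
            raise ValueError("cell area must be positive")
        for name in ("vessel_speed", "vessel_width", "vessel_draft",
                     "transit_time", "n_boats", "n_whales"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.p_strike_depth <= 1.0:
            raise ValueError("p_strike_depth must lie in [0, 1]")


def critical_radius(
    vessel_width: float,
    species: SpeciesParams,
    variant: Literal["literal", "sqrt_area"] = "literal",
) -> float:
    """Critical encounter radius: vessel beam plus a whale body term.

    The whale presents, bow-on, a target built from its total length and
    head width. The ``literal`` variant adds ``L*W/pi`` (the published
    expression read as printed); ``sqrt_area`` adds ``sqrt(L*W/pi)``, the
    dimensionally consistent radius of a circle of area ``L*W``.
    """
    if vessel_width < 0:
        raise ValueError("vessel_width must be non-negative")
    body = species.total_length * species.head_width / np.pi
    if variant == "literal":
        return vessel_width + body
    if variant == "sqrt_area":
        return float(vessel_width + np.sqrt(body))
    raise ValueError(f"unknown critical-radius variant: {variant!r}")


def mean_relative_speed(v_m: float, v_b: float) -> float:
    """Mean relative speed of two 2-D velocities with uniform headings.

    Closed form: ``(2/pi) * (v_m + v_b) * E(k)`` with
    ``k^2 = 4 v_m v_b / (v_m + v_b)^2`` and ``E`` the complete elliptic
    integral of the second kind. Limits: ``v_m = 0`` gives ``v_b``;
    ``v_m = v_b = v`` gives ``4v/pi``.
    """
    if v_m < 0 or v_b < 0:
        raise ValueError("speeds must be non-negative")
    s = v_m + v_b
    if s == 0.0:
        warnings.warn("both speeds are zero: no encounters possible", stacklevel=2)
        return 0.0
    m = 4.0 * v_m * v_b / s**2  # scipy's ellipe takes the parameter m = k^2
    return float((2.0 / np.pi) * s * ellipe(m))


def encounter_rate(r_c: float, area_s: float, v_m: float, v_b: float) -> float:
    """Per-pair encounter rate ``2 r_c E|v_rel| / S`` in 1/s."""
    if r_c <= 0:
        raise ValueError("critical radius must be positive")
    if area_s <= 0:
        raise ValueError("cell area must be positive")
    return 2.0 * r_c * mean_relative_speed(v_m, v_b) / area_s


def avoidance_probability(model: AvoidanceModel, vessel_speed_kn: float) -> float:
    """P(successful avoidance) at a vessel speed in knots."""
    if vessel_speed_kn < 0:
        raise ValueError("vessel speed must be non-negative")
    if model.variant == "none":
        return 0.0
    if model.variant == "constant":
        return model.constant_p
    # decreasing logistic, value a_max/2 at the inflection speed
    z = model.slope * (vessel_speed_kn - model.inflection_speed)
    return float(model.a_max / (1.0 + np.exp(z)))


def lethality_probability(model: LethalityModel, vessel_speed_kn: float) -> float:
    """P(death | strike) at a vessel speed in knots (logit-linear)."""
    if vessel_speed_kn < 0:
        raise ValueError("vessel speed must be non-negative")
    z = model.intercept + model.slope_per_knot * vessel_speed_kn
    return float(1.0 / (1.0 + np.exp(-z)))


def cell_mortality(
    inputs: CellModelInputs,
    species: SpeciesParams,
    avoidance: AvoidanceModel,
    lethality: LethalityModel,
    time_convention: Literal["per_vessel", "total"] = "per_vessel",
    r_c_variant: Literal["literal", "sqrt_area"] = "literal",
    swim_speed_variant: str = "mean",
) -> float:
    """Expected strike deaths in one cell over the transit period.

    Under ``per_vessel`` the transit time is the mean per-voyage time and
    the product includes ``N_b`` so ``t * N_b`` is total fleet time; under
    ``total`` the transit time is already fleet-summed and ``N_b`` is
    omitted to avoid double counting.
    """
    if inputs.n_whales == 0.0 or inputs.n_boats == 0.0:
        return 0.0
    r_c = critical_radius(inputs.vessel_width, species, r_c_variant)
    lam = encounter_rate(r_c, inputs.area_s, species.swim_speed(swim_speed_variant),
                         inputs.vessel_speed)
    speed_kn = inputs.vessel_speed / KNOT_TO_MS
    p_avoid = avoidance_probability(avoidance, speed_kn)
    p_lethal = lethality_probability(lethality, speed_kn)
    for p in (p_avoid, p_lethal, inputs.p_strike_depth):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probability factor outside [0, 1]")
    boats = inputs.n_boats if time_convention == "per_vessel" else 1.0
    if time_convention not in ("per_vessel", "total"):
        raise ValueError(f"unknown time convention: {time_convention!r}")
    return (
        lam
        * inputs.transit_time
        * inputs.p_strike_depth
        * (1.0 - p_avoid)
        * p_lethal
        * inputs.n_whales
        * boats
    )


@dataclass
class MortalitySurface:
    """Per-cell expected deaths on an analysis grid.

    ``values`` is index-aligned with cell id. ``label`` identifies the
    species / avoidance-model combination.
    """

    grid: AnalysisGrid
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_cells,):
            raise ValueError("values must have one entry per grid cell")
        if np.any(self.values < 0):
            raise ValueError("mortality values must be non-negative")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": np.arange(self.grid.n_cells),
                             "mortality": self.values})


def aggregate_mortality(monthly: Sequence[MortalitySurface] | Iterable[MortalitySurface],
                        label: str = "") -> MortalitySurface:
    """Sum per-month surfaces cell-by-cell onto one surface."""
    monthly = list(monthly)
    if not monthly:
        raise ValueError("no monthly surfaces to aggregate")
    grid = monthly[0].grid
    for s in monthly[1:]:
        if s.grid != grid:
            raise ValueError("all monthly surfaces must share one grid")
    values = np.sum([s.values for s in monthly], axis=0)
    return MortalitySurface(grid=grid, values=values, label=label or monthly[0].label)
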
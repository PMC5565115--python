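# Methods

## Model

The package treats a grid cell of area *S* (default 12 km × 12 km,
~144 km²) as a well-mixed arena in which one whale and one vessel are
points moving with independent, uniformly distributed headings. Kinetic
encounter theory then gives the per-pair rate of close approaches within
the critical radius *r_c* as λ_e = 2 r_c E|v_rel| / S. The mean relative
speed of two 2-D velocities with uniform headings has the closed form
(2/π)(v_m+v_b)E(k) with k² = 4 v_m v_b/(v_m+v_b)²; we evaluate it with
`scipy.special.ellipe` and validate it against (i) the limits v_m → 0
(giving v_b) and v_m = v_b = v (giving 4v/π) and (ii) a Monte-Carlo
oracle over random headings. Mean speeds stand in for the full speed
distributions; the whale-velocity integral collapses accordingly.

The critical radius combines the vessel beam with a whale body term
L·W/π (total length × head width). Read literally this term is an area
divided by π rather than a length; because the magnitudes it produces
for the study species (6.6–19.7 m) are nonetheless physically plausible
and match the published arithmetic, the literal form is the default and
a dimensionally consistent alternative √(L·W/π) is exposed as
`r_c_variant="sqrt_area"`. This is a genuine ambiguity in the source
formulation; both readings are implemented and labeled.

An encounter becomes a death through three conditional factors:

- **P(strike depth)** — the proportion of time the species spends at or
  above the hull draft, evaluated per cell against the pooled per-species
  time-at-depth profile (1-m bins; piecewise-linear cumulative curve;
  boundary depths count as inside). The strike zone is 1× the mean draft
  by default, extensible to 1.5× or 2× for sensitivity analysis.
- **1 − P(avoidance)** — three scenarios: a decreasing logistic in vessel
  speed with inflection at 11.8 kn (model 1), constant 0.55 (model 2),
  none (model 3). The logistic's upper asymptote (0.55) and slope
  (0.3 kn⁻¹) are not fixed by observation; the asymptote anchors to the
  observed avoidance-dive initiation rate and the slope is chosen low,
  both configurable. Because models 2 and 3 differ only by a static
  scalar, their surfaces are exactly proportional (ratio 1/0.45) — a
  property the tests assert bitwise.
- **P(mortality | v_b)** — a logit-linear lethality curve,
  logit P = −1.905 + 0.217·v (knots), transcribed from the published
  empirical strike-severity fit; both coefficients are configuration.

Per-cell expected deaths are the product
λ_e · t · P(depth) · (1−P(avoid)) · P(lethal) · N_m · N_b, computed per
month and summed. `time_convention="per_vessel"` (default) treats *t* as
mean per-voyage transit time so that t·N_b is total fleet time; the
`"total"` alternative implements the literal fleet-summed reading, which
double-counts vessels when combined with the ×N_b factor and is provided
for comparison only.

## Vessel inputs

AIS point records are filtered to underway cargo/passenger/tug vessels
faster than 1 kn with draft ≥ 1 m (per-rule removal counts are logged).
Records are grouped into voyages per vessel with a new voyage after a
6-hour reporting gap; voyage polylines are projected (spherical Albers
equal-area conic, standard parallels 33°/45°), clipped to grid cells
(length is conserved under clipping), and converted to per-cell track
length and voyage counts. Speed, draft and beam are interpolated to cell
centers by ordinary kriging: duplicate coordinates are averaged, an
isotropic variogram (spherical by default) is fitted to the binned
empirical semivariances by count-weighted least squares, the OK system
is solved over the 48 nearest samples, and predictions are clamped to
the input data range (clamps logged) with the kriging standard error
retained. A singular system falls back to inverse-distance weighting
with a warning. Transit time is track length / kriged mean speed,
divided by the voyage count under the per-vessel convention.

## Whale inputs

Density surfaces (whales/km²) are regridded to cell centers by bilinear
interpolation and multiplied by cell area to give expected whales per
cell; cells outside the source extent become zero with a warning. Tag
depth series are drift-corrected by recalibrating every 30 minutes: the
10th-shallowest reading per window is taken as zero (an order statistic
rather than the minimum, to resist errant spikes), windows with fewer
than 10 samples inherit the previous offset, and corrected depths are
clipped at zero. Corrected series are binned at 1 m into time-at-depth
and its cumulative-above form. Deployments are pooled with equal weight
per sample; equal weight per deployment can be had by resampling before
profile construction.

## Strandings

Strike-attributed records are binned into 15 equal latitudinal bins
(half-open, topmost closed; out-of-range records go to a logged overflow
bucket). Narratives are keyword-matched for carcasses found on vessel
bows or in enclosed ports — a proxy for vessel transport that would bias
the spatial pattern. Annual stranding rates divide record counts by a
10-year base: the 2006–2016 window spans 11 calendar years but the
published rates (1.0, 1.4, 1.1 whales/yr from 10, 14, 11 records) imply
a 10-year divisor, which we adopt and expose in configuration.
Extrapolation divides the rate by a carcass recovery rate: 17% (right
whale, the most buoyant species) for a minimum estimate and the
grey/killer/sperm mean (0.05, 0.065, 0.034 → 4.97%, used as the rounded
5%) for the best estimate. Reported values are rounded to whole deaths
at ≥10 and one decimal below; note that 1.1/0.17 = 6.47 rounds to 6.5
while the reference table prints 6.4 (consistent only with truncation) —
the raw quotient is always carried alongside the rounded value.

## Synthetic data

The generators produce every input format the ingest code reads, with
the statistical structure the analysis assumes: vessels transiting
straight lanes at 8–25 kn (drafts 5–18 m, beams 15–50 m, constant within
a voyage) reporting every 5 minutes with lateral scatter; whale density
as sums of Gaussian hotspots whose centers jitter with the seed while
conserving kernel mass; dive series alternating surfacings and square
foraging dives with truncated-normal durations (heavy-tailed durations
would defeat the 30-minute recalibration, which real foraging cycles do
not), plus an injected linear sensor drift for the correction to remove;
Poisson stranding counts with keyword-bearing narratives; rectangular
jurisdictions; and a linear shelf-to-abyss bathymetry. All generators
are pure functions of (scenario, seed) and byte-identical under a fixed
seed. Planted filter violations (slow pings, shallow drafts, disallowed
types) are labeled so filter tests can assert exact round trips.

What the synthetic data does not emulate: real lane geometry and traffic
seasonality, habitat-driven density structure, day/night dive
stratification, and carcass drift. Tests passing on these fixtures
demonstrate internal correctness of the machinery — not that real-data
mortality totals would be reproduced.

## Validation strategy

Because the published headline totals depend on proprietary AIS, fitted
density models and jurisdiction geometries, validation is by property:

- mean relative speed against a 10⁶-draw Monte-Carlo oracle (3 SE);
- encounter rate against counting disc entries for moving points in a
  periodic box on five parameter sets (3 SE);
- kriging exactness at sample points with zero nugget and range-bound
  predictions;
- end-to-end: on a one-lane-through-one-hotspot scenario with vessel
  parameters held constant, the pipeline's total matches a discrete-event
  simulation (closest-approach encounter detection between a moving ship
  and moving whales, Bernoulli depth/avoidance/lethality thinning) within
  3× the Poisson-scale Monte-Carlo error across three seeds. The
  simulated whale field is redrawn per cell transit so the population
  stays statistically stationary, matching the static-density assumption
  of the analytic model; within a transit whales move ballistically.
- conservation (cells → months → zones) and model-2/3 proportionality
  asserted to machine precision; strike-zone multiplier monotonicity
  asserted across 1×/1.5×/2×.

Desk-reproducible arithmetic (stranding extrapolations, best recovery
rate, PBR ratios) is asserted exactly against the published figures.

## Parameters and defaults

| parameter | default | units | note |
|---|---|---|---|
| cell size | 12,000 | m | ~144 km² cells |
| species L×W | 20.9×2.96 / 13.5×3.21 / 18.48×2.65 | m | blue / humpback / fin |
| PBR | 2.3 / 11 / 16 | whales/yr | annual removal limits |
| swim speed (mean/travel/ARS) | 1.0,1.8,0.5 / 1.1,1.6,0.6 / 1.3,2.5,0.8 | m/s | satellite-tag literature ranges; totals are insensitive to this axis |
| avoidance | logistic(a_max 0.55, slope 0.3/kn, inflection 11.8 kn); 0.55; 0 | — | models 1–3 |
| lethality | logit P = −1.905 + 0.217·v | v in kn | published empirical fit |
| AIS filters | >1 kn, ≥1 m draft, cargo/passenger/tug, underway | — | |
| voyage gap | 6 | h | new voyage after a longer gap |
| kriging | spherical variogram, auto WLS fit, 48 neighbors | — | clamped to data range |
| zero-offset window / rank | 30 min / 10th shallowest | — | |
| recovery rates | 0.17 min-scenario; mean(0.05, 0.065, 0.034) best | — | |
| conversion | 1 kn = 0.514444 m/s | — | centralized in `units` |

Default scenario problem sizes (a 120 km × 120 km grid of 100 cells, two
lanes totaling ~180 voyages/month over six months, ~10⁴ AIS records,
24-hour dive series at 5-s sampling) were chosen so a full pipeline run
completes in seconds while every estimator operates well inside its
asymptotic regime; the end-to-end validation scenario uses 2,000 voyages
per seed to hold the Monte-Carlo error on simulated deaths near 10%.

## Known limitations

- 2-D encounter geometry: depth enters only through the time-at-depth
  factor, not through a 3-D closest-approach calculation.
- Whale density is held static across months; movement does not deplete
  or displace density (a per-month density hook exists but defaults off).
- The avoidance logistic's slope and asymptote are weakly constrained by
  observation; conclusions that depend on model 1's spatial pattern
  should be checked against models 2/3.
- Ordinary kriging assumes second-order stationarity of the vessel
  fields; strongly laned traffic violates isotropy, and the range clamp
  is the guard against the resulting extrapolation artifacts.
- The ~12-km grid under-resolves density gradients near ports, where
  real strike risk concentrates.
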
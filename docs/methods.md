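# Methods

## Scope and model structure

The package estimates the fraction of a coformulant's annual use tonnage
released to air, agricultural soil, surface water and waste when plant
protection products are applied, and converts those fractions into mass
flows. It covers the two application routes that differ environmentally:
spraying of diluted products, and direct application of granules or treated
seeds to soil. The outputs are regional-scale emission inputs for external
multimedia fate models; no environmental concentrations (PECs) are computed
here, and runoff/drainage — which such fate models handle themselves — is
deliberately excluded from the surface-water factor (the module has no
runoff parameter at all).

## Volatility banding

Air release from spraying is governed by vapor pressure, the only
volatility descriptor that is a standard REACH data requirement. Substances
are assigned to half-open bands (lower-closed, upper-open) with boundaries
at 1e-5, 1e-4, 1e-3 and 1e-2 Pa; 0.01 Pa and above counts as volatile, the
conventional cutoff for environmental (hours-to-days) timescales, so a
substance at exactly 0.01 Pa receives F_air = 1. The banded spray air
factors are 0.01 / 0.1 / 0.2 / 0.5 / 1 in increasing vapor-pressure order.
Vapor pressures are used at face value in Pa; the temperature basis
(20 vs 25 °C) is the caller's responsibility.

## Evaporation model

The banded air factors are checked against a continuous model: a log-linear
regression of evaporation rate on vapor pressure,

    ln ER = intercept + slope · ln VP,   defaults intercept = 12.2, slope = 0.933

with ER in µg/m²/h and VP in Pa, valid over roughly 1e-4 to 3e4 Pa (the
range of the underlying field and laboratory data). Holding that rate
constant over a 24-h window after a 1 kg/ha application (1 kg/ha =
1e5 µg/m²) gives a calculated air fraction

    F_air(calc) = duration_h · ER / (1e5 · AR),   capped at 1.

Reading the defining formula as this dimensionless ratio is the only
precedence that makes the quantity a fraction; the uncapped value is also
exposed for diagnostics. No source-depletion correction is applied — the
regression gives a rate, not a decay curve, and a constant-rate 24-h window
is conservative relative to the short actual field activity.

The conservatism report scans each band on a log-spaced grid (default 200
points per decade, open-ended bands extended three decades past the last
finite boundary). Because F_air(calc) is strictly increasing in VP, each
band's worst case sits at its upper edge; the grid therefore includes a
point just inside that edge. With the default parameters the banded values
are conservative (band ≥ calculated) everywhere except the 0.001–0.01 Pa
band: just below 0.01 Pa the calculated fraction reaches ≈ 0.65 against the
banded 0.5, an absolute shortfall of ≈ 0.15 and a relative one of ≈ 23 %.
Because "about 20 % underestimate" is ambiguous between the absolute and
relative reading, the report exposes both rather than asserting one.

## Surface-water factor

The regional scenario is a 1-ha treated field (10 000 m²) adjacent to a
1 m × 100 m water body (100 m²): the water surface is 1 % of the field
area. Direct overspray is excluded (not good agricultural practice), so
only spray drift contributes:

    F_surface_water = drift_fraction · water_area / field_area.

Shipped 90th-percentile drift fractions by crop class: arable 2.8 %,
orchards/citrus/olives (late applications) 15.7 %, early pome/stone fruit
29.2 %, hops 19.3 %, aerial 33.2 %. The orchard class is the selected
realistic regional worst case (0.157 × 0.01 = 0.00157 → 0.002); the three
higher-drift classes are computable but flagged as not representative at
the regional scale (rare, minor-crop, or derogation-only uses).

Release factors are rounded to one significant figure, half away from zero.
The rule is inferred from the single published instance (0.00157 → 0.002);
always-up rounding would be equally consistent with that one case, and the
raw value is always reported alongside the rounded one so the choice is
auditable.

## Engine and version semantics

A release-factor set is the quadruple (F_air, F_soil, F_surface_water,
F_waste) for one method/band. Waste is carried as a fourth fraction even
though the headline tables omit it, so emission totals are complete: 1e-4
for granular/seed packaging residue (read across from the plastic-additives
emission scenario for >40 µm powders), and 0 for spray, where rinsate is
returned to the sprayer tank — the <0.01 % container-residue bound is kept
as metadata (`SPRAY_CONTAINER_RESIDUE_BOUND`) rather than as a factor.

Version 4 (built in) is *decoupled*: each factor is an independent worst
case and the sum may exceed 1 (e.g. 0.5 + 1 + 0.002 in the transition
band). The mass-balance checker flags this as intentional conservatism,
never an error. Earlier versions are *coupled* (sum ≤ 1 per band, tolerance
1e-9 for floating point only) and their exact tables are not part of the
public record; they load from JSON config and are validated against the
coupled constraint at load time. Version 0 exposes the ERC 8d defaults
(1, 1, 0.2) for comparison; it is method-agnostic. A granular lookup for a
volatile substance (VP ≥ 0.01 Pa) is answered but flagged — such uses are
unlikely (product-stability arguments) but the row exists.

## Emissions

Emission mass per compartment = tonnage × regional_fraction × factor,
componentwise, with no renormalization when factors sum above 1 (that is
the decoupled semantics). `regional_fraction` defaults to 1 — allocating
the whole market tonnage to the region — because regional allocation
conventions belong to the downstream fate model. Aggregation across uses is
a componentwise sum with provenance preserved.

## Inventory cleaning

Records are discarded in a fixed order — polymer, then no vapor-pressure
data, then implausible value — chosen for determinism and logged per
record, so the input partitions exactly into the final set plus discard
categories and cleaning is idempotent. Two deliberate choices:

* inorganics with *no* data are retained and assigned to the lowest band
  (the TiO₂-style data-free assignment); inorganics with a measured vapor
  pressure keep their measured band;
* "implausible" is not defined in the public record, so the default window
  is (1e-12, 1e8) Pa — generously outside any measurable coformulant value
  — and is configurable.

Histograms use the band edges below 0.01 Pa and optional decade bins above
it, which is how the distribution is usually displayed.

## Synthetic inventories

Real coformulant inventories show a U-shaped log-VP distribution: mostly
clearly nonvolatile solids and clearly volatile solvents, few transition
substances. The generator emulates this with the simplest adequate model, a
two-component mixture of normals in log10 VP with modes at −7 (inside the
lowest band) and +3 (above 10 Pa), sd 1.2 decades, equal weights; flags for
inorganic (5 %), polymer (3 %, mutually exclusive with inorganic), missing
VP (5 %) and liquid state (40 %) are independent draws, and tonnages span
0.1–1000 t/y log-uniformly. All draws come from one seeded generator; there
is no unseeded API, and a fixed spec reproduces a byte-identical CSV.

What this does and does not show: passing tests demonstrate the pipeline's
correctness on inventories with the assumed mixture structure, not that any
real market inventory has particular band counts — the published
166-substance data set is not public, bin heights were never printed as
numbers, and the generator is a structural emulation, not a fit.

## Numerical choices and problem sizes

* Band membership uses exact float comparisons against decade boundaries;
  no epsilon is applied, so 0.01 is volatile by construction.
* Conservatism grid: 200 points/decade; the upper-edge sample is pulled
  inside the band by a relative 1e-12 to respect half-open membership.
* Coupled-sum tolerance 1e-9; any real excess is a violation.
* Property tests scan ~2000–3000-point log grids over 1e-8–1e6 Pa;
  generator checks use n = 2000 (U-shape, determinism) and n = 10 000
  (volatile-fraction calibration within 3 standard errors), sizes at which
  the binomial standard errors are small enough to make the checks sharp
  while the whole suite runs in seconds.

## Known limitations

* No drift-curve interpolation by distance or growth stage — only the
  published crop-class percentiles.
* No risk-management measures (buffer zones, drift-reducing nozzles): none
  can be assumed for the generic coformulant case.
* No indoor/greenhouse differentiation and no professional/consumer split;
  outdoor field use is the covering worst case.
* Inorganic/polymer status is an input flag, never inferred from structure.
* The evaporation regression is applied outside its fitted range when bands
  below 1e-4 Pa are scanned; this only makes the low bands more obviously
  conservative, but the extrapolation should be kept in mind for diagnostic
  use of the continuous curve.
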
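# sperc

Environmental release factors and compartment emissions for substances used
as **coformulants in plant protection products** (PPPs) — the solvents,
surfactants, fillers and other intentionally added components that are not
the active substance.

Under REACH, hazardous coformulants above 10 t/y need a regional-scale
environmental exposure assessment. The default environmental release
category for outdoor processing aids (ERC 8d) assumes worst-case release
factors of F_air = 1, F_soil = 1, F_surface_water = 0.2. Sector-specific
environmental release categories (SpERCs) refine these using the operational
reality of PPP use. This package implements that refinement for the two
application routes that matter:

* **spray application** (SpERC 8d.2.v4): F_air banded by vapor pressure VP
  (Pa), with band boundaries at 1e-5, 1e-4, 1e-3 and 1e-2 Pa and factors
  0.01 / 0.1 / 0.2 / 0.5 / 1; F_soil = 1 below the 0.01 Pa volatility cutoff
  and 0 above it; F_surface_water = 0.002 in every band; F_waste = 0
  (container rinsate is returned to the sprayer).
* **granular products / treated seeds** (SpERC 8d.1.v4): F_air = 0,
  F_soil = 1 (even for volatile substances, should they be used),
  F_surface_water = 0, F_waste = 1e-4 (0.01 % packaging residue).

Around those tables the package provides:

* the **evaporation model** justifying the air bands — the log-linear
  regression `ln ER = 12.2 + 0.933 ln VP` (ER in µg/m²/h, VP in Pa) turned
  into a calculated 24-h air fraction `F_air(calc) = 24·ER / (1e5·AR)` at a
  1 kg/ha application rate, plus a conservatism report comparing banded
  versus calculated values;
* the **spray-drift geometry** behind the surface-water factor — a 1-ha
  field adjacent to a 1 m × 100 m water body, crop-class 90th-percentile
  drift (arable 2.8 %, orchard/citrus/olive 15.7 %, and higher classes for
  reference), giving `F_sw = drift × water_area/field_area`;
* **tonnage apportionment** — per-compartment emission masses (t/y) from
  use tonnage × regional fraction × factors, with aggregation across uses;
* **inventory tooling** — CSV/TSV ingest, the polymer / no-data /
  implausible-value cleaning rules (data-free inorganics are retained in the
  lowest band), and volatility-band histograms;
* a **seeded synthetic inventory generator** reproducing the U-shaped
  log-VP distribution real coformulant inventories show, so everything is
  testable offline.

## Worked example

Python:

```python
>>> from sperc import get_release_factors, compartment_emissions
>>> rfs = get_release_factors("spray", 5e-3, version=4)
>>> rfs.f_air, rfs.f_soil, rfs.f_surface_water, rfs.f_waste
(0.5, 1.0, 0.002, 0.0)
>>> est = compartment_emissions(100.0, rfs)   # 100 t/y sprayed
>>> est.to_air, est.to_soil, est.to_surface_water, est.to_waste
(50.0, 100.0, 0.2, 0.0)
```

A substance at 5e-3 Pa sits in the 0.001–0.01 Pa transition band: half the
tonnage is assumed lost to air within 24 h, all of it is (also) assumed to
reach soil — the version-4 factors are deliberately decoupled worst cases,
so they may sum above 1 — 0.2 % drifts to surface water, and nothing goes
to waste.

The same from the command line, including the surface-water derivation
chain:

```
$ sperc derive-drift --scenario orchard_late_citrus_olive
{
  "crop_class": "orchard_late_citrus_olive",
  "drift_fraction": 0.157,
  "field_area_m2": 10000.0,
  "water_area_m2": 100.0,
  "area_ratio": 0.01,
  "f_surface_water_raw": 0.00157,
  "f_surface_water_rounded": 0.002,
  "regional_worst_case": true
}
```

15.7 % of the applied dose drifts, the water body is 1 % of the field area,
so 0.00157 of the tonnage reaches water; rounded to one significant figure
this is the 0.002 used in the spray table. Other subcommands: `classify`,
`factors`, `emit`, `emit-batch`, `list`, `validate-bands`, `profile`,
`synth` (see `sperc --help`).

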
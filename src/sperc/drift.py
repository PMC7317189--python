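"""Spray-drift derivation of the surface-water release factor.

The regional scenario places a 1-ha treated field (10 000 m^2) next to a
1 m x 100 m water body (100 m^2), so the water surface is 1% of the field
area.  Direct overspray is assumed not to occur; only drift (a crop-class
90th-percentile fraction of the application rate deposited on the water
surface) contributes:

    F_surface_water = drift_fraction * water_area / field_area

With the realistic worst-case orchard drift of 15.7% this gives
0.157 * 0.01 = 0.00157, rounded for the published table to 0.002.  Runoff
and drainage are deliberately absent from this factor: they are modeled
downstream by the regional fate model, and this module has no parameter
for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

from .core import ValidationError

__all__ = [
    "CropClass",
    "DriftScenario",
    "SCENARIOS",
    "f_surface_water",
    "round_release_factor",
]


class CropClass(str, Enum):
    ARABLE = "arable"
    ORCHARD_LATE_CITRUS_OLIVE = "orchard_late_citrus_olive"
    POME_STONE_EARLY = "pome_stone_early"
    HOPS = "hops"
    AERIAL = "aerial"
    CUSTOM = "custom"


@dataclass(frozen=True)
class DriftScenario:
    """Crop-class drift percentile plus field/water-body geometry."""

    crop_class: CropClass
    #: fraction of the application rate deposited on the water surface
    drift_fraction: float
    field_area_m2: float = 10_000.0
    water_area_m2: float = 100.0
    #: crop classes with higher drift than the selected realistic worst case
    #: (rare, minor, or derogation-only uses) are shipped but flagged
    regional_worst_case: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.drift_fraction <= 1.0):
            raise ValidationError(
                f"drift_fraction {self.drift_fraction} not in [0, 1]"
            )
        if self.field_area_m2 <= 0 or self.water_area_m2 <= 0:
            raise ValidationError("field and water areas must be positive")


#: Shipped 90th-percentile drift scenarios by crop class.  The orchard
#: (late applications, citrus, olives) value 15.7% is the selected realistic
#: regional worst case; higher-drift classes are retained for computation but
#: flagged as not representative at the regional scale.
SCENARIOS = {
    CropClass.ARABLE: DriftScenario(CropClass.ARABLE, 0.028),
    CropClass.ORCHARD_LATE_CITRUS_OLIVE: DriftScenario(
        CropClass.ORCHARD_LATE_CITRUS_OLIVE, 0.157
    ),
    CropClass.POME_STONE_EARLY: DriftScenario(
        CropClass.POME_STONE_EARLY, 0.292, regional_worst_case=False
    ),
    CropClass.HOPS: DriftScenario(CropClass.HOPS, 0.193, regional_worst_case=False),
    CropClass.AERIAL: DriftScenario(CropClass.AERIAL, 0.332, regional_worst_case=False),
}


def f_surface_water(sc: DriftScenario) -> float:
    """Surface-water release fraction: drift scaled by the area ratio."""
    return sc.drift_fraction * (sc.water_area_m2 / sc.field_area_m2)


def round_release_factor(x: float) -> float:
    """Round a release fraction to one significant figure, half away from zero.

    This reproduces the published rounding 0.00157 -> 0.002.  0 and 1 are
    fixed points.
    """
    if not (0.0 <= x <= 1.0):
        raise ValidationError(f"release factor {x} not in [0, 1]")
    if x == 0.0 or x == 1.0:
        return float(x)
    exponent = math.floor(math.log10(x))
    quantum = Decimal(1).scaleb(exponent)
    rounded = Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP)
    # one-sig-fig rounding can carry, e.g. 0.95 -> 1.0e0; re-derive if so
    if rounded != 0 and math.floor(rounded.adjusted()) != exponent:
        rounded = rounded.quantize(Decimal(1).scaleb(rounded.adjusted()))
    return min(float(rounded), 1.0)
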
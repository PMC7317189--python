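"""Domain types and vapor-pressure banding shared by all other modules.

The release factors to air used in the spray SpERC are banded by substance
vapor pressure (Pa).  Band membership is lower-closed / upper-open
(``lower <= vp < upper``), so 0.01 Pa itself falls in the volatile band.
Vapor pressures are taken at face value in Pa; the temperature basis
(20 vs 25 degC) is the caller's responsibility.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Optional, Sequence

__all__ = [
    "PhysicalState",
    "ApplicationMethod",
    "Substance",
    "VolatilityBand",
    "ValidationError",
    "VOLATILE_CUTOFF_PA",
    "DEFAULT_PLAUSIBILITY_WINDOW_PA",
    "default_bands",
    "load_bands",
    "bands_to_json",
    "classify_volatility",
    "applicable_methods",
]

#: Above this vapor pressure a substance is treated as fully volatile over the
#: assessment timescale (hours to days), the convention used in EU exposure
#: guidance.
VOLATILE_CUTOFF_PA = 0.01

#: Default plausibility window for measured vapor pressures, Pa.  Values
#: outside it are treated as data errors during inventory cleaning.  The
#: window is a repository default, configurable by the caller.
DEFAULT_PLAUSIBILITY_WINDOW_PA = (1e-12, 1e8)


class ValidationError(ValueError):
    """Raised when an input violates a domain precondition."""


class PhysicalState(str, Enum):
    SOLID = "solid"
    LIQUID = "liquid"
    UNKNOWN = "unknown"


class ApplicationMethod(str, Enum):
    """How the plant-protection product reaches the field.

    ``GRANULAR`` covers both granular products and treated seeds.
    """

    SPRAY = "spray"
    GRANULAR = "granular"


@dataclass(frozen=True)
class VolatilityBand:
    """A half-open vapor-pressure interval with its banded air release factor.

    ``lower_pa <= vp < upper_pa``; the lowest band has ``lower_pa = 0`` and
    the highest ``upper_pa = inf``.
    """

    lower_pa: float
    upper_pa: float
    label: str
    f_air_spray: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower_pa < self.upper_pa):
            raise ValidationError(
                f"band {self.label!r}: need 0 <= lower < upper, "
                f"got [{self.lower_pa}, {self.upper_pa})"
            )
        if not (0.0 <= self.f_air_spray <= 1.0):
            raise ValidationError(
                f"band {self.label!r}: f_air_spray {self.f_air_spray} not in [0, 1]"
            )

    def contains(self, vp_pa: float) -> bool:
        return self.lower_pa <= vp_pa < self.upper_pa


@dataclass
class Substance:
    """One coformulant: an intentionally added PPP component other than the
    active substance (solvent, surfactant, filler, ...)."""

    id: str
    name: str = ""
    vapor_pressure_pa: Optional[float] = None
    physical_state: PhysicalState = PhysicalState.UNKNOWN
    is_inorganic: bool = False
    is_polymer: bool = False
    use_tonnage_t_per_y: Optional[float] = None
    #: force both application methods regardless of physical state (e.g. a
    #: liquid claimed in a solid formulation)
    force_both_methods: bool = False
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.vapor_pressure_pa is not None:
            vp = self.vapor_pressure_pa
            if not (isinstance(vp, (int, float)) and math.isfinite(vp) and vp > 0):
                raise ValidationError(
                    f"substance {self.id!r}: vapor pressure must be positive "
                    f"and finite, got {vp!r}"
                )
        if self.use_tonnage_t_per_y is not None and self.use_tonnage_t_per_y < 0:
            raise ValidationError(
                f"substance {self.id!r}: tonnage must be non-negative"
            )


# --------------------------------------------------------------------------
# Band table


def _validate_partition(bands: Sequence[VolatilityBand]) -> tuple:
    bands = tuple(sorted(bands, key=lambda b: b.lower_pa))
    if not bands:
        raise ValidationError("band table is empty")
    if bands[0].lower_pa != 0.0:
        raise ValidationError("lowest band must start at 0")
    if not math.isinf(bands[-1].upper_pa):
        raise ValidationError("highest band must extend to +inf")
    for a, b in zip(bands, bands[1:]):
        if a.upper_pa != b.lower_pa:
            raise ValidationError(
                f"bands {a.label!r} and {b.label!r} do not tile: "
                f"{a.upper_pa} != {b.lower_pa}"
            )
    for a, b in zip(bands, bands[1:]):
        if b.f_air_spray < a.f_air_spray:
            raise ValidationError(
                "f_air_spray must be non-decreasing with vapor pressure"
            )
    return bands


def load_bands(source) -> tuple:
    """Load a band table from a JSON file path, file object, or parsed list.

    The JSON schema is a list of ``{"lower_pa": .., "upper_pa": ..,
    "label": .., "f_air_spray": ..}``; ``upper_pa`` may be the string
    ``"inf"``.  The table must partition (0, inf).
    """
    if isinstance(source, (list, tuple)):
        raw = source
    elif hasattr(source, "read"):
        raw = json.load(source)
    else:
        with open(source) as fh:
            raw = json.load(fh)
    bands = [
        VolatilityBand(
            lower_pa=float(r["lower_pa"]),
            upper_pa=float(r["upper_pa"]),
            label=str(r["label"]),
            f_air_spray=float(r["f_air_spray"]),
        )
        for r in raw
    ]
    return _validate_partition(bands)


def bands_to_json(bands: Sequence[VolatilityBand]) -> list:
    """Serialize a band table to the JSON-compatible schema of load_bands."""
    return [
        {
            "lower_pa": b.lower_pa,
            "upper_pa": "inf" if math.isinf(b.upper_pa) else b.upper_pa,
            "label": b.label,
            "f_air_spray": b.f_air_spray,
        }
        for b in bands
    ]


def default_bands() -> tuple:
    """The shipped version-4 spray band table (boundaries at 1e-5..1e-2 Pa)."""
    with resources.files("sperc.data").joinpath("bands_v4.json").open() as fh:
        return load_bands(fh)


def classify_volatility(
    vp_pa: float,
    bands: Optional[Sequence[VolatilityBand]] = None,
    substance_id: str = "<anonymous>",
) -> VolatilityBand:
    """Return the unique volatility band containing ``vp_pa``.

    Raises :class:`ValidationError` (naming the substance) for missing,
    non-positive or non-finite vapor pressures.
    """
    if vp_pa is None:
        raise ValidationError(f"substance {substance_id!r}: vapor pressure missing")
    if not (isinstance(vp_pa, (int, float)) and math.isfinite(vp_pa) and vp_pa > 0):
        raise ValidationError(
            f"substance {substance_id!r}: vapor pressure must be positive and "
            f"finite, got {vp_pa!r}"
        )
    if bands is None:
        bands = default_bands()
    for band in bands:
        if band.contains(vp_pa):
            return band
    raise ValidationError(
        f"substance {substance_id!r}: no band contains {vp_pa} Pa"
    )  # pragma: no cover - unreachable for a valid partition


def applicable_methods(s: Substance) -> frozenset:
    """Application methods a substance must be assessed for.

    A solid (or unknown-state) substance must be assumed to be potentially
    applied both as a spray and as a granule/treated seed; a liquid can in
    practice only appear in spray formulations unless explicitly overridden.
    """
    if s.force_both_methods or s.physical_state is not PhysicalState.LIQUID:
        return frozenset({ApplicationMethod.SPRAY, ApplicationMethod.GRANULAR})
    return frozenset({ApplicationMethod.SPRAY})
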
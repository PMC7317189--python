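"""Tonnage-to-compartment emission mass flows.

An emission estimate is the componentwise product of the annual use tonnage,
a regional allocation fraction, and the release-factor set.  No
renormalization is applied even when the factors sum above 1: version-4
factors are decoupled worst cases by design, and the resulting totals are
deliberately conservative inputs to downstream multimedia fate models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import ValidationError
from .engine import ReleaseFactorSet

__all__ = ["EmissionEstimate", "compartment_emissions", "aggregate_emissions"]


@dataclass(frozen=True)
class EmissionEstimate:
    """Per-compartment mass flows (tonnes/year) for one or more uses."""

    to_air: float
    to_soil: float
    to_surface_water: float
    to_waste: float
    #: provenance: tuple of (substance id, method, version/sperc id, band)
    sources: tuple = ()

    def __post_init__(self) -> None:
        for name in ("to_air", "to_soil", "to_surface_water", "to_waste"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def total(self) -> float:
        return self.to_air + self.to_soil + self.to_surface_water + self.to_waste

    def as_dict(self) -> dict:
        return {
            "to_air_t_y": self.to_air,
            "to_soil_t_y": self.to_soil,
            "to_surface_water_t_y": self.to_surface_water,
            "to_waste_t_y": self.to_waste,
            "sources": [list(s) for s in self.sources],
        }


def compartment_emissions(
    tonnage_t_y: float,
    rfs: ReleaseFactorSet,
    regional_fraction: float = 1.0,
    substance_id: str = "<anonymous>",
    method: str = "",
) -> EmissionEstimate:
    """Emission masses for one use: tonnage x regional fraction x factors."""
    if tonnage_t_y < 0:
        raise ValidationError(f"tonnage must be non-negative, got {tonnage_t_y}")
    if not (0.0 <= regional_fraction <= 1.0):
        raise ValidationError(
            f"regional_fraction {regional_fraction} not in [0, 1]"
        )
    base = tonnage_t_y * regional_fraction
    return EmissionEstimate(
        to_air=base * rfs.f_air,
        to_soil=base * rfs.f_soil,
        to_surface_water=base * rfs.f_surface_water,
        to_waste=base * rfs.f_waste,
        sources=((substance_id, method, rfs.sperc_id, rfs.band_label),),
    )


def aggregate_emissions(estimates: Sequence[EmissionEstimate]) -> EmissionEstimate:
    """Componentwise sum across uses; provenance is concatenated."""
    if not estimates:
        raise ValidationError("cannot aggregate an empty list of estimates")
    sources: tuple = ()
    for e in estimates:
        sources = sources + e.sources
    return EmissionEstimate(
        to_air=sum(e.to_air for e in estimates),
        to_soil=sum(e.to_soil for e in estimates),
        to_surface_water=sum(e.to_surface_water for e in estimates),
        to_waste=sum(e.to_waste for e in estimates),
        sources=sources,
    )
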
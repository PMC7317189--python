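"""Continuous evaporation-rate model behind the banded air release factors.

A log-linear regression relates the evaporation rate ER (ug/m^2/h) of a
sprayed substance to its vapor pressure VP (Pa):

    ln ER = intercept + slope * ln VP        (defaults 12.2, 0.933)

Integrating that rate over a 24-h window at a 1 kg/ha application rate gives
a calculated air release fraction

    F_air(calc) = duration_h * ER / (1e5 * AR)

(1 kg/ha = 1e5 ug/m^2, so the ratio is dimensionless), capped at 1.  The
banded F_air values of the spray SpERC are meant to sit above this curve;
the conservatism report quantifies where they do not.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import ValidationError, VolatilityBand, default_bands

__all__ = [
    "EvaporationParams",
    "BandConservatism",
    "ConservatismReport",
    "evaporation_rate",
    "f_air_continuous",
    "band_conservatism_report",
]

#: ug/m^2 deposited by a 1 kg/ha application.
_UG_PER_M2_PER_KG_HA = 1e5


@dataclass(frozen=True)
class EvaporationParams:
    """Parameters of the evaporation regression and the release window.

    intercept
        regression intercept, in ln(ug/m^2/h).
    slope
        regression slope per ln(Pa); must be positive (evaporation increases
        with vapor pressure).
    duration_h
        averaging window for the air release, hours.  24 h is deliberately
        conservative relative to the short actual field activity.
    application_rate_kg_ha
        single application rate, kg/ha.
    """

    intercept: float = 12.2
    slope: float = 0.933
    duration_h: float = 24.0
    application_rate_kg_ha: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError("slope must be positive")
        if self.duration_h <= 0:
            raise ValidationError("duration_h must be positive")
        if self.application_rate_kg_ha <= 0:
            raise ValidationError("application_rate_kg_ha must be positive")


def _check_vp(vp_pa) -> None:
    arr = np.asarray(vp_pa, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValidationError(f"vapor pressure must be positive and finite, got {vp_pa!r}")


def evaporation_rate(vp_pa, params: EvaporationParams = EvaporationParams()):
    """Evaporation rate ER in ug/m^2/h at vapor pressure ``vp_pa`` (Pa).

    Accepts a scalar or array; natural logarithms throughout.
    """
    _check_vp(vp_pa)
    arr = np.asarray(vp_pa, dtype=float)
    er = np.exp(params.intercept + params.slope * np.log(arr))
    return float(er) if np.isscalar(vp_pa) or arr.ndim == 0 else er


def f_air_continuous(
    vp_pa,
    params: EvaporationParams = EvaporationParams(),
    cap: bool = True,
):
    """Calculated 24-h air release fraction at vapor pressure ``vp_pa``.

    ``duration_h * ER / (1e5 * AR)``, capped at 1 unless ``cap=False``
    (the uncapped value is useful for diagnostics).
    """
    er = evaporation_rate(vp_pa, params)
    raw = params.duration_h * np.asarray(er) / (
        _UG_PER_M2_PER_KG_HA * params.application_rate_kg_ha
    )
    out = np.minimum(raw, 1.0) if cap else raw
    return float(out) if np.isscalar(vp_pa) or out.ndim == 0 else out


@dataclass
class BandConservatism:
    """Comparison of one band's F_air with the calculated curve."""

    label: str
    band_f_air: float
    max_calculated_f_air: float
    #: calculated minus band value, clipped at 0 (0 where the band is
    #: conservative, i.e. band >= calculated)
    max_deficit: float
    vp_at_max_deficit: float

    @property
    def max_relative_deficit(self) -> float:
        """Deficit relative to the calculated value (0 when no deficit)."""
        if self.max_deficit <= 0:
            return 0.0
        return self.max_deficit / self.max_calculated_f_air

    @property
    def conservative(self) -> bool:
        return self.max_deficit <= 0


@dataclass
class ConservatismReport:
    """Per-band conservatism of a band table against the calculated curve."""

    bands: list
    params: EvaporationParams
    #: curve samples (vp_pa, f_air_calc) suitable for re-plotting
    curve: list = field(default_factory=list)

    @property
    def non_conservative_bands(self) -> list:
        return [b for b in self.bands if not b.conservative]

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": {
                    "intercept": self.params.intercept,
                    "slope": self.params.slope,
                    "duration_h": self.params.duration_h,
                    "application_rate_kg_ha": self.params.application_rate_kg_ha,
                },
                "bands": [
                    {
                        "label": b.label,
                        "band_f_air": b.band_f_air,
                        "max_calculated_f_air": b.max_calculated_f_air,
                        "max_deficit": b.max_deficit,
                        "max_relative_deficit": b.max_relative_deficit,
                        "vp_at_max_deficit": b.vp_at_max_deficit,
                        "conservative": b.conservative,
                    }
                    for b in self.bands
                ],
            },
            indent=2,
        )

    def curve_table(self) -> str:
        """Two-column table (vp_pa, f_air_calc), tab separated, for re-plotting."""
        lines = ["vp_pa\tf_air_calc"]
        lines += [f"{vp:.8e}\t{f:.8e}" for vp, f in self.curve]
        return "\n".join(lines) + "\n"


def band_conservatism_report(
    bands: Optional[Sequence[VolatilityBand]] = None,
    params: EvaporationParams = EvaporationParams(),
    grid_points_per_decade: int = 200,
    open_end_decades: float = 3.0,
) -> ConservatismReport:
    """Compare banded F_air values with the calculated continuous curve.

    Each band is scanned on a log-spaced grid (``grid_points_per_decade``
    points per decade); unbounded ends are extended ``open_end_decades``
    decades beyond the last finite boundary.  Because the calculated curve
    is strictly increasing in vp, within-band maxima occur at each band's
    upper edge; the grid includes a point just inside that edge.
    """
    if bands is None:
        bands = default_bands()
    bands = list(bands)
    if not bands:
        raise ValidationError("empty band list")
    if grid_points_per_decade < 10:
        raise ValidationError("need at least 10 grid points per decade")

    finite = [b.lower_pa for b in bands if b.lower_pa > 0]
    finite += [b.upper_pa for b in bands if math.isfinite(b.upper_pa)]
    lo_edge = min(finite) / 10**open_end_decades
    hi_edge = max(finite) * 10**open_end_decades

    results = []
    curve: list = []
    for band in sorted(bands, key=lambda b: b.lower_pa):
        lo = band.lower_pa if band.lower_pa > 0 else lo_edge
        hi = band.upper_pa if math.isfinite(band.upper_pa) else hi_edge
        n = max(2, int(round(grid_points_per_decade * math.log10(hi / lo))))
        grid = np.logspace(math.log10(lo), math.log10(hi), n)
        # upper edge is exclusive: pull the last point just inside the band
        grid[-1] = hi * (1 - 1e-12) if math.isfinite(band.upper_pa) else hi
        fcalc = f_air_continuous(grid, params)
        deficit = np.clip(fcalc - band.f_air_spray, 0.0, None)
        i = int(np.argmax(deficit))
        results.append(
            BandConservatism(
                label=band.label,
                band_f_air=band.f_air_spray,
                max_calculated_f_air=float(np.max(fcalc)),
                max_deficit=float(deficit[i]),
                vp_at_max_deficit=float(grid[i]),
            )
        )
        curve.extend(zip(grid.tolist(), np.asarray(fcalc).tolist()))

    return ConservatismReport(bands=results, params=params, curve=curve)
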
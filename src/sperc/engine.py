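"""Release-factor lookup for a substance, application method and SpERC version.

The version-4 tables are built in:

* spray (SpERC 8d.2.v4): F_air banded by vapor pressure (0.01/0.1/0.2/0.5/1),
  F_soil = 1 below the 0.01 Pa volatility cutoff and 0 above it (full
  volatilization assumed), F_surface_water = 0.002 in every band, F_waste = 0
  (container rinsate is returned to the sprayer tank; the <0.01% residue
  bound is carried as metadata).
* granular / treated seeds (SpERC 8d.1.v4): F_air = 0 and
  F_surface_water = 0 in both vapor-pressure rows, F_soil = 1 even for
  volatile substances should they be used, F_waste = 0.0001 (0.01% packaging
  residue, read across from the plastic-additives emission scenario).
* the ERC 8d defaults (1, 1, 0.2) are retrievable as version 0 for
  comparison.

Version semantics: version 4 is *decoupled* — the factor sum may exceed 1 by
design (each compartment is a stand-alone worst case).  Earlier versions are
*coupled* (the sum may not exceed 1) and their exact tables are not published
in the main documentation; they can be loaded from a JSON config, which is
validated against the coupled constraint at load time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

from .core import (
    ApplicationMethod,
    ValidationError,
    VolatilityBand,
    VOLATILE_CUTOFF_PA,
    classify_volatility,
    default_bands,
)

__all__ = [
    "ReleaseFactorSet",
    "SpercVersionTable",
    "MassBalanceReport",
    "get_release_factors",
    "mass_balance_check",
    "list_sperc",
    "load_version_table",
    "builtin_version_table",
    "SPRAY_CONTAINER_RESIDUE_BOUND",
]

#: Upper bound on formulation retained in a properly rinsed spray container.
#: The rinsate is returned to the sprayer, so the spray waste factor is 0;
#: the bound is kept as metadata for audits.
SPRAY_CONTAINER_RESIDUE_BOUND = 1e-4

#: Tolerance on the factor sum in coupled mode: floating point only, any
#: real excess over 1 is a violation.
_COUPLED_TOL = 1e-9

_FLAG_VOLATILE_GRANULAR = (
    "volatile-granular: granular/seed use of a substance with vapor pressure "
    ">= 0.01 Pa is considered unlikely; factors returned unchanged"
)
_FLAG_DECOUPLED = "intentional conservatism: factor sum exceeds 1 (decoupled factors)"


@dataclass(frozen=True)
class ReleaseFactorSet:
    """The four compartment fractions for one SpERC / version / band."""

    f_air: float
    f_soil: float
    f_surface_water: float
    f_waste: float
    sperc_id: str
    band_label: str
    flags: tuple = ()

    def __post_init__(self) -> None:
        for name in ("f_air", "f_soil", "f_surface_water", "f_waste"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} not in [0, 1]")

    @property
    def factor_sum(self) -> float:
        return self.f_air + self.f_soil + self.f_surface_water + self.f_waste

    def as_dict(self) -> dict:
        return {
            "f_air": self.f_air,
            "f_soil": self.f_soil,
            "f_surface_water": self.f_surface_water,
            "f_waste": self.f_waste,
            "sperc_id": self.sperc_id,
            "band_label": self.band_label,
            "flags": list(self.flags),
        }


@dataclass
class SpercVersionTable:
    """All (method, band) release-factor rows for one SpERC version."""

    version: int
    #: rows[method] is a list of (VolatilityBand-like bounds, ReleaseFactorSet)
    rows: dict
    mass_balance_mode: str  # "coupled" | "decoupled"

    def __post_init__(self) -> None:
        if self.mass_balance_mode not in ("coupled", "decoupled"):
            raise ValidationError(
                f"unknown mass_balance_mode {self.mass_balance_mode!r}"
            )
        if self.mass_balance_mode == "coupled":
            for method, rows in self.rows.items():
                for band, rfs in rows:
                    if rfs.factor_sum > 1.0 + _COUPLED_TOL:
                        raise ValidationError(
                            f"version {self.version} is coupled but "
                            f"{method.value}/{band.label!r} has factor sum "
                            f"{rfs.factor_sum} > 1"
                        )

    def lookup(self, method: ApplicationMethod, vp_pa: float) -> ReleaseFactorSet:
        if method not in self.rows:
            # method-agnostic tables (the ERC 8d defaults) carry one row set
            if len(self.rows) == 1:
                method = next(iter(self.rows))
            else:
                raise ValidationError(
                    f"version {self.version} has no rows for method {method.value!r}"
                )
        for band, rfs in self.rows[method]:
            if band.contains(vp_pa):
                return rfs
        raise ValidationError(
            f"version {self.version}/{method.value}: no band contains {vp_pa} Pa"
        )

    def to_json(self) -> str:
        rows = []
        for method, pairs in self.rows.items():
            for band, rfs in pairs:
                rows.append(
                    {
                        "method": method.value,
                        "lower_pa": band.lower_pa,
                        "upper_pa": "inf" if math.isinf(band.upper_pa) else band.upper_pa,
                        "band_label": band.label,
                        **{
                            k: rfs.as_dict()[k]
                            for k in ("f_air", "f_soil", "f_surface_water", "f_waste")
                        },
                        "sperc_id": rfs.sperc_id,
                    }
                )
        return json.dumps(
            {
                "version": self.version,
                "mass_balance_mode": self.mass_balance_mode,
                "rows": rows,
            },
            indent=2,
        )


def _band_for_row(lower, upper, label) -> VolatilityBand:
    # a standalone interval (engine rows need containment, not a partition,
    # and row f_air is not a spray band factor) -> f_air_spray unused, set 0
    return VolatilityBand(lower_pa=lower, upper_pa=upper, label=label, f_air_spray=0.0)


def _table_from_rows(version, mode, raw_rows) -> SpercVersionTable:
    rows: dict = {}
    for r in raw_rows:
        method = ApplicationMethod(r["method"])
        band = _band_for_row(
            float(r["lower_pa"]), float(r["upper_pa"]), str(r["band_label"])
        )
        rfs = ReleaseFactorSet(
            f_air=float(r["f_air"]),
            f_soil=float(r["f_soil"]),
            f_surface_water=float(r["f_surface_water"]),
            f_waste=float(r.get("f_waste", 0.0)),
            sperc_id=str(r.get("sperc_id", f"8d.?.v{version}")),
            band_label=str(r["band_label"]),
        )
        rows.setdefault(method, []).append((band, rfs))
    for method in rows:
        rows[method].sort(key=lambda br: br[0].lower_pa)
    return SpercVersionTable(version=version, rows=rows, mass_balance_mode=mode)


def load_version_table(source) -> SpercVersionTable:
    """Load a SpERC version table from a JSON path/file object/parsed dict.

    Coupled tables (versions before 4) are validated at load time: the
    factor sum must not exceed 1 in any row.
    """
    if isinstance(source, dict):
        raw = source
    elif hasattr(source, "read"):
        raw = json.load(source)
    else:
        with open(source) as fh:
            raw = json.load(fh)
    return _table_from_rows(
        int(raw["version"]), str(raw["mass_balance_mode"]), raw["rows"]
    )


def builtin_version_table(version: int = 4) -> SpercVersionTable:
    """The shipped tables: version 4 (current) and version 0 (ERC 8d defaults)."""
    name = {4: "sperc_v4.json", 0: "erc8d.json"}.get(version)
    if name is None:
        raise ValidationError(
            f"version {version} is not built in (available: 0, 4); "
            "supply a config table for other versions"
        )
    with resources.files("sperc.data").joinpath(name).open() as fh:
        return load_version_table(fh)


def get_release_factors(
    method: ApplicationMethod,
    vp_pa: float,
    version: int = 4,
    table: Optional[SpercVersionTable] = None,
) -> ReleaseFactorSet:
    """Complete release-factor set for an application method and vapor pressure.

    ``table`` overrides the built-in tables (needed for versions other than
    0 and 4).  A granular request for a volatile substance (vp >= 0.01 Pa)
    is answered but flagged, since such uses are considered unlikely.
    """
    method = ApplicationMethod(method)
    # validates positivity/finiteness and raises a named error
    classify_volatility(vp_pa)
    if table is None:
        table = builtin_version_table(version)
    elif table.version != version:
        raise ValidationError(
            f"supplied table is version {table.version}, requested {version}"
        )
    rfs = table.lookup(method, vp_pa)
    if method is ApplicationMethod.GRANULAR and vp_pa >= VOLATILE_CUTOFF_PA:
        rfs = replace(rfs, flags=rfs.flags + (_FLAG_VOLATILE_GRANULAR,))
    return rfs


@dataclass
class MassBalanceReport:
    factor_sum: float
    mode: str
    violation: bool
    flags: tuple = ()


def mass_balance_check(rfs: ReleaseFactorSet, mode: str) -> MassBalanceReport:
    """Check the factor sum S = f_air + f_soil + f_surface_water + f_waste.

    Coupled mode: S > 1 (beyond float tolerance) is a violation.  Decoupled
    mode: S > 1 is flagged as intentional conservatism, never an error.
    """
    if mode not in ("coupled", "decoupled"):
        raise ValidationError(f"unknown mass balance mode {mode!r}")
    s = rfs.factor_sum
    if mode == "coupled":
        return MassBalanceReport(
            factor_sum=s, mode=mode, violation=s > 1.0 + _COUPLED_TOL
        )
    flags = (_FLAG_DECOUPLED,) if s > 1.0 else ()
    return MassBalanceReport(factor_sum=s, mode=mode, violation=False, flags=flags)


def list_sperc(
    version: int = 4, table: Optional[SpercVersionTable] = None
) -> list:
    """All (method, band, ReleaseFactorSet) rows of a version, in band order."""
    if table is None:
        table = builtin_version_table(version)
    out = []
    for method in sorted(table.rows, key=lambda m: m.value, reverse=True):
        for band, rfs in table.rows[method]:
            out.append((method, band, rfs))
    return out
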
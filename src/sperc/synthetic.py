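"""Seeded generator of synthetic coformulant inventories.

Real coformulant inventories show a U-shaped log vapor-pressure
distribution: most substances are either clearly nonvolatile (fillers,
surfactants, polym-adjacent solids well below 1e-5 Pa) or clearly volatile
(solvents above 10 Pa), with only a minority in the banded transition
region.  The generator emulates that structure with a two-component
mixture of lognormals (modes inside the lowest band and in the >10 Pa
region), plus independent flags for inorganics, polymers, missing data and
physical state, so every downstream module is testable without any external
data set.

This is a structural emulation, not a statistical fit — the published
distribution is shown as a figure, not a table of counts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import ValidationError

__all__ = ["InventorySpec", "generate_inventory", "inventory_to_csv"]

_COLUMNS = [
    "id",
    "name",
    "vapor_pressure_pa",
    "physical_state",
    "is_inorganic",
    "is_polymer",
    "use_tonnage_t_per_y",
]


@dataclass(frozen=True)
class InventorySpec:
    """Parameters of the synthetic inventory.

    ``low_mode_log10pa``/``high_mode_log10pa`` place the two mixture modes
    (defaults log10 Pa = -7 and +3, i.e. inside the lowest band and above
    10 Pa); ``high_fraction`` is the volatile component weight.
    """

    n: int
    seed: int
    low_mode_log10pa: float = -7.0
    high_mode_log10pa: float = 3.0
    mode_sd_log10: float = 1.2
    high_fraction: float = 0.5
    p_inorganic: float = 0.05
    p_polymer: float = 0.03
    p_missing_vp: float = 0.05
    p_liquid: float = 0.4

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError("n must be positive")
        if self.mode_sd_log10 <= 0:
            raise ValidationError("mode_sd_log10 must be positive")
        for name in (
            "high_fraction",
            "p_inorganic",
            "p_polymer",
            "p_missing_vp",
            "p_liquid",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} not in [0, 1]")
        if self.p_inorganic + self.p_polymer > 1.0:
            raise ValidationError("p_inorganic + p_polymer must not exceed 1")


def generate_inventory(spec: InventorySpec) -> pd.DataFrame:
    """Draw a synthetic inventory as a DataFrame in the CSV schema.

    log10(VP) is a two-component normal mixture; flags are independent
    draws; inorganics and polymers are mutually exclusive.  Fully
    reproducible for a fixed spec (seeded generator, fixed column order).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    is_high = rng.random(n) < spec.high_fraction
    mode = np.where(is_high, spec.high_mode_log10pa, spec.low_mode_log10pa)
    log10_vp = rng.normal(mode, spec.mode_sd_log10)
    vp = 10.0 ** log10_vp

    # one categorical draw keeps inorganic/polymer mutually exclusive
    u = rng.random(n)
    is_inorganic = u < spec.p_inorganic
    is_polymer = (~is_inorganic) & (u < spec.p_inorganic + spec.p_polymer)

    missing = rng.random(n) < spec.p_missing_vp
    liquid = rng.random(n) < spec.p_liquid
    # annual use tonnage spanning niche to commodity uses
    tonnage = 10.0 ** rng.uniform(-1.0, 3.0, n)

    vp_col = [None if m else float(v) for m, v in zip(missing, vp)]
    df = pd.DataFrame(
        {
            "id": [f"SYN{i:05d}" for i in range(n)],
            "name": [f"synthetic coformulant {i}" for i in range(n)],
            "vapor_pressure_pa": vp_col,
            "physical_state": np.where(liquid, "liquid", "solid"),
            "is_inorganic": is_inorganic,
            "is_polymer": is_polymer,
            "use_tonnage_t_per_y": np.round(tonnage, 4),
        },
        columns=_COLUMNS,
    )
    return df


def inventory_to_csv(df: pd.DataFrame, path=None) -> Optional[str]:
    """Serialize an inventory DataFrame to the CSV dialect read_inventory
    accepts; returns the text when ``path`` is None."""
    buf = io.StringIO()
    out = df.copy()
    out["vapor_pressure_pa"] = [
        "" if v is None else repr(float(v)) for v in out["vapor_pressure_pa"]
    ]
    out.to_csv(buf, index=False)
    text = buf.getvalue()
    if path is None:
        return text
    with open(path, "w", newline="") as fh:
        fh.write(text)
    return None
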
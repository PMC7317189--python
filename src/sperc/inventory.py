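"""Ingest, clean, band and summarize coformulant inventories.

The cleaning workflow mirrors how a real coformulant data set is assembled
from registration data: records that are polymers are discarded, records
with no vapor-pressure data are discarded unless they are inorganic
(inorganics are retained, data-free, and assigned to the lowest volatility
band — e.g. TiO2), and records with implausible values are discarded.  Every
disposition is logged per record, so input records partition exactly into
the final set plus the discard categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .core import (
    DEFAULT_PLAUSIBILITY_WINDOW_PA,
    PhysicalState,
    Substance,
    VolatilityBand,
    classify_volatility,
    default_bands,
)

__all__ = [
    "RawRecord",
    "CleaningLog",
    "read_inventory",
    "clean_inventory",
    "band_histogram",
    "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = ("id", "vapor_pressure_pa")
_OPTIONAL_COLUMNS = (
    "name",
    "physical_state",
    "is_inorganic",
    "is_polymer",
    "use_tonnage_t_per_y",
)

_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f", ""}


@dataclass
class RawRecord:
    """One inventory row as read, before cleaning.  ``error`` carries a
    record-level parse problem (collected, not fatal)."""

    id: str
    name: str = ""
    vapor_pressure_pa: Optional[float] = None
    physical_state: PhysicalState = PhysicalState.UNKNOWN
    is_inorganic: bool = False
    is_polymer: bool = False
    use_tonnage_t_per_y: Optional[float] = None
    error: Optional[str] = None


@dataclass
class CleaningLog:
    n_input: int = 0
    n_discarded_no_data: int = 0
    n_discarded_implausible: int = 0
    n_discarded_polymer: int = 0
    n_assigned_inorganic: int = 0
    n_final: int = 0
    #: record id -> disposition string
    dispositions: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_discarded_no_data": self.n_discarded_no_data,
            "n_discarded_implausible": self.n_discarded_implausible,
            "n_discarded_polymer": self.n_discarded_polymer,
            "n_assigned_inorganic": self.n_assigned_inorganic,
            "n_final": self.n_final,
            "dispositions": dict(self.dispositions),
        }


def _parse_vp(raw) -> Optional[float]:
    """Parse a vapor-pressure cell: scientific notation, comma decimal
    separators, and blank/NA as missing."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    if isinstance(raw, (int, float)):
        return float(raw)
    text = str(raw).strip()
    if not text or text.lower() in {"na", "nan", "none", "null"}:
        return None
    # locale-safe: a comma with no period is a decimal separator
    if "," in text and "." not in text:
        text = text.replace(",", ".")
    return float(text)  # may raise ValueError -> collected by caller


def _parse_bool(raw) -> bool:
    if isinstance(raw, bool):
        return raw
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return False
    text = str(raw).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValueError(f"unparseable boolean {raw!r}")


def read_inventory(path, dialect: Optional[str] = None) -> list:
    """Read a CSV/TSV inventory into :class:`RawRecord` objects.

    ``dialect`` is "csv" or "tsv"; by default it is inferred from the file
    extension (``.tsv``/``.tab`` -> tab) falling back to comma.  Missing
    required columns raise immediately; unparseable cells are collected on
    the record (``record.error``), never fatal.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"inventory is missing required columns: {missing}")

    records = []
    for _, row in df.iterrows():
        rec = RawRecord(id=str(row["id"]), name=str(row.get("name", "") or ""))
        try:
            rec.vapor_pressure_pa = _parse_vp(row["vapor_pressure_pa"])
            state = str(row.get("physical_state", "") or "").strip().lower()
            rec.physical_state = (
                PhysicalState(state) if state else PhysicalState.UNKNOWN
            )
            rec.is_inorganic = _parse_bool(row.get("is_inorganic"))
            rec.is_polymer = _parse_bool(row.get("is_polymer"))
            tonnage = row.get("use_tonnage_t_per_y")
            rec.use_tonnage_t_per_y = _parse_vp(tonnage) if tonnage else None
        except ValueError as exc:
            rec.error = str(exc)
        records.append(rec)
    return records


def clean_inventory(
    records: Sequence[RawRecord],
    plausibility_window_pa: tuple = DEFAULT_PLAUSIBILITY_WINDOW_PA,
) -> tuple:
    """Apply the discard rules and return (substances, CleaningLog).

    Rules, in order, per record: polymer -> discard; no vapor-pressure data
    -> discard unless inorganic (retained, assigned the lowest band);
    vapor pressure outside the plausibility window -> discard.  Records with
    parse errors count as no-data.  Deterministic given input order.
    """
    lo, hi = plausibility_window_pa
    log = CleaningLog(n_input=len(records))
    substances = []
    for rec in records:
        if rec.is_polymer:
            log.n_discarded_polymer += 1
            log.dispositions[rec.id] = "discarded:polymer"
            continue
        vp = None if rec.error else rec.vapor_pressure_pa
        if vp is None:
            if rec.is_inorganic:
                log.n_assigned_inorganic += 1
                log.dispositions[rec.id] = "retained:inorganic-lowest-band"
                substances.append(
                    Substance(
                        id=rec.id,
                        name=rec.name,
                        vapor_pressure_pa=None,
                        physical_state=rec.physical_state,
                        is_inorganic=True,
                        use_tonnage_t_per_y=rec.use_tonnage_t_per_y,
                    )
                )
            else:
                log.n_discarded_no_data += 1
                log.dispositions[rec.id] = "discarded:no-data"
            continue
        if not (lo < vp < hi) or vp <= 0 or not math.isfinite(vp):
            log.n_discarded_implausible += 1
            log.dispositions[rec.id] = "discarded:implausible"
            continue
        log.dispositions[rec.id] = "retained"
        substances.append(
            Substance(
                id=rec.id,
                name=rec.name,
                vapor_pressure_pa=vp,
                physical_state=rec.physical_state,
                is_inorganic=rec.is_inorganic,
                use_tonnage_t_per_y=rec.use_tonnage_t_per_y,
            )
        )
    log.n_final = len(substances)
    return substances, log


def _substance_band(s: Substance, bands) -> VolatilityBand:
    if s.vapor_pressure_pa is None:
        # cleaned inorganics without data sit in the lowest band
        return min(bands, key=lambda b: b.lower_pa)
    return classify_volatility(s.vapor_pressure_pa, bands, substance_id=s.id)


def band_histogram(
    substances: Sequence[Substance],
    bands=None,
    split_volatile_decades: bool = False,
) -> dict:
    """Counts per volatility band (ordered dict label -> count).

    With ``split_volatile_decades`` the open-ended volatile band is split
    into decade bins for display (0.01-0.1, 0.1-1, ...), as in the published
    distribution plot.  Counts always sum to ``len(substances)``.
    """
    if bands is None:
        bands = default_bands()
    bands = sorted(bands, key=lambda b: b.lower_pa)
    counts = {b.label: 0 for b in bands}
    volatile = bands[-1]
    volatile_vps = []
    for s in substances:
        band = _substance_band(s, bands)
        counts[band.label] += 1
        if band is volatile and s.vapor_pressure_pa is not None:
            volatile_vps.append(s.vapor_pressure_pa)

    if not split_volatile_decades:
        return counts

    out = {b.label: counts[b.label] for b in bands[:-1]}
    if volatile_vps:
        top = math.floor(math.log10(max(volatile_vps))) + 1
    else:
        top = math.floor(math.log10(volatile.lower_pa)) + 1
    edges = [volatile.lower_pa]
    while edges[-1] < 10.0 ** top:
        edges.append(edges[-1] * 10.0)
    for lo_e, hi_e in zip(edges, edges[1:]):
        label = f"{lo_e:g} to <{hi_e:g}"
        out[label] = sum(1 for vp in volatile_vps if lo_e <= vp < hi_e)
    return out
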
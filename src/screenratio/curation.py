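"""Standardization and filtering of compound activity records.

Heterogeneous potency measurements (Ki, pKi, IC50) are converted to a
common Ki scale in nM, multiple measurements per compound are merged,
and compounds are labeled active/inactive against a potency cutoff
(default 100 nM, strict). Molecular-weight filtering and structure-based
deduplication mirror the standard curation steps applied to bioactivity
database extracts before fingerprinting.

Unit conventions
----------------
* Ki and IC50 values are in nM.
* pKi is dimensionless, defined on the molar scale: pKi = -log10(Ki [M]),
  hence Ki [nM] = 10 ** (9 - pKi).
* IC50 is converted with the Kalliokoski factor: Ki = IC50 / 2.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

MEASUREMENT_TYPES = ("Ki", "pKi", "IC50")

#: Potency cutoff below which a compound is considered active, in nM.
DEFAULT_ACTIVITY_THRESHOLD_NM = 100.0

#: Molecular-weight window (strict bounds), in Daltons.
DEFAULT_MW_BOUNDS = (200.0, 700.0)

#: Divisor applied to IC50 values to estimate Ki.
IC50_TO_KI_DIVISOR = 2.0


@dataclass(frozen=True)
class ActivityRecord:
    """One raw potency measurement for one compound.

    ``value`` is in nM for Ki/IC50 and dimensionless for pKi.
    """

    compound_id: str
    measurement_type: str
    value: float
    structure: str | None = None
    mw: float | None = None
    target_id: str | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if self.measurement_type not in MEASUREMENT_TYPES:
            raise ValueError(
                f"unknown measurement_type {self.measurement_type!r}; "
                f"expected one of {MEASUREMENT_TYPES}"
            )
        if self.measurement_type in ("Ki", "IC50") and not self.value > 0:
            raise ValueError(
                f"{self.measurement_type} must be positive, got {self.value}"
            )


@dataclass(frozen=True)
class CuratedCompound:
    """A compound with a standardized Ki (nM) and an activity label."""

    compound_id: str
    ki_nM: float
    label: str
    mw: float | None = None
    structure: str | None = None

    def __post_init__(self) -> None:
        if self.label not in ("active", "inactive"):
            raise ValueError(f"label must be 'active' or 'inactive', got {self.label!r}")
        if not self.ki_nM > 0:
            raise ValueError(f"ki_nM must be positive, got {self.ki_nM}")


def standardize_activity(record: ActivityRecord) -> float:
    """Convert one measurement to Ki in nM.

    Ki passes through unchanged, pKi maps to ``10 ** (9 - pKi)`` and IC50
    is halved (Kalliokoski conversion).
    """
    if record.measurement_type == "Ki":
        return float(record.value)
    if record.measurement_type == "pKi":
        return 10.0 ** (9.0 - record.value)
    if record.measurement_type == "IC50":
        return float(record.value) / IC50_TO_KI_DIVISOR
    raise ValueError(f"unknown measurement_type {record.measurement_type!r}")


def aggregate_measurements(records: Sequence[ActivityRecord]) -> float:
    """Merge several measurements of one compound into a single Ki (nM).

    Returns the median of the standardized Ki values; the median resists
    the occasional discordant assay. All records must share a compound_id.
    """
    if not records:
        raise ValueError("cannot aggregate an empty list of records")
    ids = {r.compound_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records span multiple compounds: {sorted(ids)}")
    return float(statistics.median(standardize_activity(r) for r in records))


def label_activity(
    ki_nM: float, threshold_nM: float = DEFAULT_ACTIVITY_THRESHOLD_NM
) -> str:
    """Label a compound active iff its Ki is strictly below the cutoff."""
    if not ki_nM > 0:
        raise ValueError(f"ki_nM must be positive, got {ki_nM}")
    return "active" if ki_nM < threshold_nM else "inactive"


def filter_by_mw(
    compounds: Iterable[CuratedCompound],
    lo_Da: float = DEFAULT_MW_BOUNDS[0],
    hi_Da: float = DEFAULT_MW_BOUNDS[1],
    keep_unknown: bool = False,
) -> list[CuratedCompound]:
    """Keep compounds with ``lo_Da < mw < hi_Da`` (both bounds strict).

    Order is preserved. A compound without a molecular weight raises
    unless ``keep_unknown`` is set, in which case it passes through.
    """
    kept = []
    for c in compounds:
        if c.mw is None:
            if keep_unknown:
                kept.append(c)
                continue
            raise ValueError(f"compound {c.compound_id} has no molecular weight")
        if lo_Da < c.mw < hi_Da:
            kept.append(c)
    return kept


def _structure_key(c: CuratedCompound) -> str:
    return c.structure if c.structure else c.compound_id


def deduplicate(compounds: Iterable[CuratedCompound]) -> list[CuratedCompound]:
    """Drop duplicate structures, keeping the first occurrence.

    The duplicate key is the canonical structure string when present and
    the compound id otherwise; order is preserved.
    """
    seen: set[str] = set()
    out = []
    for c in compounds:
        key = _structure_key(c)
        if key not in seen:
            seen.add(key)
            out.append(c)
    return out


def curate(
    records: Sequence[ActivityRecord],
    threshold_nM: float = DEFAULT_ACTIVITY_THRESHOLD_NM,
    mw_bounds: tuple[float, float] | None = DEFAULT_MW_BOUNDS,
    keep_unknown_mw: bool = False,
) -> list[CuratedCompound]:
    """Full curation pipeline: aggregate, label, MW-filter, deduplicate.

    Records are grouped by compound_id (first-appearance order), each
    group's measurements are standardized and merged by median, labels
    are assigned against ``threshold_nM``, the MW window is applied when
    ``mw_bounds`` is given, and duplicate structures are removed.
    """
    groups: dict[str, list[ActivityRecord]] = {}
    for r in records:
        groups.setdefault(r.compound_id, []).append(r)

    compounds = []
    for cid, grp in groups.items():
        ki = aggregate_measurements(grp)
        mw = next((r.mw for r in grp if r.mw is not None), None)
        structure = next((r.structure for r in grp if r.structure), None)
        compounds.append(
            CuratedCompound(
                compound_id=cid,
                ki_nM=ki,
                label=label_activity(ki, threshold_nM),
                mw=mw,
                structure=structure,
            )
        )
    if mw_bounds is not None:
        compounds = filter_by_mw(
            compounds, mw_bounds[0], mw_bounds[1], keep_unknown=keep_unknown_mw
        )
    return deduplicate(compounds)


def read_activity_table(path) -> list[ActivityRecord]:
    """Read activity records from delimited text (comma or tab, sniffed).

    Expected columns: compound_id, measurement_type, value and optionally
    structure, mw, target_id.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"compound_id", "measurement_type", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            ActivityRecord(
                compound_id=str(d["compound_id"]),
                measurement_type=str(d["measurement_type"]),
                value=float(d["value"]),
                structure=_opt_str(d.get("structure")),
                mw=_opt_float(d.get("mw")),
                target_id=_opt_str(d.get("target_id")),
            )
        )
    return records


def write_curated_table(compounds: Sequence[CuratedCompound], path) -> None:
    """Write curated compounds as CSV with compound_id, ki_nM, label, mw."""
    pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in compounds],
            "ki_nM": [c.ki_nM for c in compounds],
            "label": [c.label for c in compounds],
            "mw": [c.mw for c in compounds],
        }
    ).to_csv(path, index=False)


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    s = str(v)
    return s if s and s.lower() != "nan" else None


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, str) and not v.strip()):
        return None
    f = float(v)
    return None if pd.isna(f) else f
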
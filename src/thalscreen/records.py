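"""Domain types for complete-blood-count screening records and CSV I/O.

Units are fixed to the clinical reporting conventions used throughout the
package: hemoglobin in g/dL, red-cell count in 10^6/uL, MCV in fL, MCH in pg,
MCHC in g/dL, hematocrit in %, RDW in %, serum iron and TIBC in ug/dL, HbA2
as a percentage of total hemoglobin.  No unit conversion is performed on
input: every discriminant-index threshold in :mod:`thalscreen.indices`
assumes these units.

Missing optional analytes are represented as ``None``, never as sentinel
numbers, so that RDW-dependent indices fail loudly instead of silently
computing on a placeholder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "CBCRecord",
    "IronPanel",
    "HPLCResult",
    "SubjectRecord",
    "CohortTable",
    "CohortSchemaError",
    "CohortParseError",
    "TRUE_CLASSES",
    "COLUMNS",
    "COLUMN_ALIASES",
    "validate_record",
    "read_cohort",
    "write_cohort",
]

#: Recognised carrier-state labels (known only for synthetic cohorts).
TRUE_CLASSES = ("btt", "other_variant", "normal", "ida")

#: Canonical CSV column order for cohort interchange files.
COLUMNS = (
    "subject_id", "hb", "rbc", "mcv", "mch", "mchc", "hct", "rdw",
    "serum_iron", "tibc", "hba2", "variant_window", "true_class",
    "spouse_tested",
)

#: Case-insensitive header aliases accepted by :func:`read_cohort`.
COLUMN_ALIASES = {
    "id": "subject_id",
    "sample_id": "subject_id",
    "hgb": "hb",
    "hemoglobin": "hb",
    "rbc_count": "rbc",
    "haematocrit": "hct",
    "hematocrit": "hct",
    "rdw_cv": "rdw",
    "iron": "serum_iron",
    "hb_a2": "hba2",
    "hba2_percent": "hba2",
}

_MANDATORY = ("subject_id", "hb", "rbc", "mcv", "mch")


class CohortSchemaError(ValueError):
    """A cohort CSV is missing a mandatory column or has a malformed header."""


class CohortParseError(ValueError):
    """A cohort CSV cell could not be parsed; the message names the row."""


@dataclass(frozen=True)
class CBCRecord:
    """One subject's red-cell panel.

    ``mchc``, ``hct`` and ``rdw`` are optional; RDW is required only by the
    RDW-using indices (RDWI, Green & King, Ricerca, RDW itself).
    """

    subject_id: str
    hb: float
    rbc: float
    mcv: float
    mch: float
    mchc: Optional[float] = None
    hct: Optional[float] = None
    rdw: Optional[float] = None


@dataclass(frozen=True)
class IronPanel:
    """Serum iron (ug/dL) and total iron-binding capacity (ug/dL)."""

    serum_iron: float
    tibc: float

    @property
    def tsat(self) -> float:
        """Transferrin saturation in percent, 100 * serum_iron / TIBC."""
        return 100.0 * self.serum_iron / self.tibc


@dataclass(frozen=True)
class HPLCResult:
    """HbA2 fraction (%) and an optional label for a non-A2 abnormal peak."""

    hba2: float
    variant_window: Optional[str] = None


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: CBC plus optional iron panel, HPLC result and metadata."""

    cbc: CBCRecord
    iron: Optional[IronPanel] = None
    hplc: Optional[HPLCResult] = None
    true_class: Optional[str] = None
    spouse_tested: Optional[bool] = None

    @property
    def subject_id(self) -> str:
        return self.cbc.subject_id


@dataclass
class CohortTable:
    """Ordered collection of subjects with unique ids.

    ``provenance`` is free text recording where the table came from (a file
    path, or a generator seed for synthetic cohorts).
    """

    records: list[SubjectRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


def _check_positive(name: str, value: float, messages: list[str]) -> None:
    if not math.isfinite(value) or value <= 0:
        messages.append(f"{name} must be a positive finite number, got {value}")


def validate_record(r: CBCRecord) -> list[str]:
    """Return violation messages for ``r``; empty iff all invariants hold.

    Total over correctly-typed inputs: never raises, whatever the numbers.
    """
    messages: list[str] = []
    for name in ("hb", "rbc", "mcv", "mch"):
        _check_positive(name, getattr(r, name), messages)
    if r.rdw is not None and not (
        math.isfinite(r.rdw) and 0 < r.rdw < 100
    ):
        messages.append(f"rdw must lie in (0, 100), got {r.rdw}")
    return messages


def validate_iron(p: IronPanel) -> list[str]:
    messages: list[str] = []
    if not (math.isfinite(p.serum_iron) and p.serum_iron >= 0):
        messages.append(f"serum_iron must be >= 0, got {p.serum_iron}")
    if not (math.isfinite(p.tibc) and p.tibc > 0):
        messages.append(f"tibc must be > 0, got {p.tibc}")
    elif not 0 <= p.tsat <= 100:
        messages.append(f"transferrin saturation must lie in [0, 100], got {p.tsat}")
    return messages


def validate_hplc(h: HPLCResult) -> list[str]:
    if not (math.isfinite(h.hba2) and 0 <= h.hba2 <= 100):
        return [f"hba2 must lie in [0, 100], got {h.hba2}"]
    return []


# ---------------------------------------------------------------------------
# CSV I/O


def _canonical_columns(raw: Iterable[str]) -> dict[str, str]:
    """Map raw header names to canonical column names (case-insensitive)."""
    mapping: dict[str, str] = {}
    for col in raw:
        key = str(col).strip().lower()
        key = COLUMN_ALIASES.get(key, key)
        if key in COLUMNS:
            mapping[col] = key
    return mapping


def _cell(row, col: str):
    val = row.get(col)
    if val is None:
        return None
    if isinstance(val, str):
        val = val.strip()
        return val or None
    if isinstance(val, float) and math.isnan(val):
        return None
    return val


def _num(row, col: str, idx: int) -> Optional[float]:
    raw = _cell(row, col)
    if raw is None:
        return None
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise CohortParseError(
            f"row {idx}: column {col!r}: cannot parse {raw!r} as a number"
        ) from None


_BOOL = {"true": True, "1": True, "yes": True,
         "false": False, "0": False, "no": False}


def _bool(row, col: str, idx: int) -> Optional[bool]:
    raw = _cell(row, col)
    if raw is None:
        return None
    if isinstance(raw, bool):
        return raw
    key = str(raw).strip().lower()
    if key in _BOOL:
        return _BOOL[key]
    raise CohortParseError(f"row {idx}: column {col!r}: cannot parse {raw!r} as a boolean")


def read_cohort(path: str | Path, **csv_options) -> CohortTable:
    """Read a cohort CSV into a :class:`CohortTable`, preserving row order.

    The header must name the mandatory columns (subject_id, hb, rbc, mcv,
    mch), case-insensitively and modulo :data:`COLUMN_ALIASES`.  Optional
    columns that are absent, or blank on a given row, leave the field unset.
    Extra ``csv_options`` are passed through to :func:`pandas.read_csv`.

    Raises :class:`CohortSchemaError` for a missing mandatory column and
    :class:`CohortParseError` (naming the row) for a non-numeric cell.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, **csv_options)
    mapping = _canonical_columns(frame.columns)
    frame = frame.rename(columns=mapping)[
        [c for c in COLUMNS if c in mapping.values()]
    ]
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise CohortSchemaError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )

    records: list[SubjectRecord] = []
    for idx, row in enumerate(frame.to_dict(orient="records")):
        sid = _cell(row, "subject_id")
        if sid is None:
            raise CohortParseError(f"row {idx}: subject_id is blank")
        numbers = {}
        for col in ("hb", "rbc", "mcv", "mch"):
            val = _num(row, col, idx)
            if val is None:
                raise CohortParseError(f"row {idx}: mandatory column {col!r} is blank")
            numbers[col] = val
        cbc = CBCRecord(
            subject_id=str(sid),
            **numbers,
            mchc=_num(row, "mchc", idx),
            hct=_num(row, "hct", idx),
            rdw=_num(row, "rdw", idx),
        )
        serum_iron = _num(row, "serum_iron", idx)
        tibc = _num(row, "tibc", idx)
        if (serum_iron is None) != (tibc is None):
            raise CohortParseError(
                f"row {idx}: serum_iron and tibc must be given together"
            )
        iron = IronPanel(serum_iron, tibc) if serum_iron is not None else None
        hba2 = _num(row, "hba2", idx)
        variant = _cell(row, "variant_window")
        hplc = HPLCResult(hba2, variant) if hba2 is not None else None
        true_class = _cell(row, "true_class")
        if true_class is not None and true_class not in TRUE_CLASSES:
            raise CohortParseError(
                f"row {idx}: true_class {true_class!r} not in {TRUE_CLASSES}"
            )
        records.append(
            SubjectRecord(
                cbc=cbc, iron=iron, hplc=hplc, true_class=true_class,
                spouse_tested=_bool(row, "spouse_tested", idx),
            )
        )
    return CohortTable(records=records, provenance=str(path))


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def to_dataframe(table: CohortTable) -> pd.DataFrame:
    """Flatten a cohort to a DataFrame with the canonical column layout."""
    rows = []
    for rec in table:
        c = rec.cbc
        rows.append({
            "subject_id": c.subject_id, "hb": c.hb, "rbc": c.rbc,
            "mcv": c.mcv, "mch": c.mch, "mchc": c.mchc, "hct": c.hct,
            "rdw": c.rdw,
            "serum_iron": rec.iron.serum_iron if rec.iron else None,
            "tibc": rec.iron.tibc if rec.iron else None,
            "hba2": rec.hplc.hba2 if rec.hplc else None,
            "variant_window": rec.hplc.variant_window if rec.hplc else None,
            "true_class": rec.true_class,
            "spouse_tested": rec.spouse_tested,
        })
    return pd.DataFrame(rows, columns=list(COLUMNS))


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV that :func:`read_cohort` round-trips bit-exactly.

    Floats are written with ``repr`` (shortest form that re-reads to the same
    double), so any value with at most a few decimal digits survives a
    write/read cycle unchanged.
    """
    path = Path(path)
    frame = to_dataframe(table)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(COLUMNS) + "\n")
        for row in frame.itertuples(index=False):
            fh.write(",".join(_fmt(v) for v in row) + "\n")


def relabel(record: SubjectRecord, **changes) -> SubjectRecord:
    """Return a copy of ``record`` with top-level fields replaced."""
    return replace(record, **changes)
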
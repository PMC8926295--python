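"""Registry and evaluation of 16 red-cell discriminant indices.

Each index is an arithmetic combination of CBC analytes proposed in the
hematology literature to separate beta-thalassemia trait (BTT, high-normal
red-cell count with microcytosis) from iron-deficiency anemia (low count,
high anisocytosis).  For each index the registry pins:

* the formula, taken from the index's defining publication (cited inline) —
  for England & Fraser, the constant 3.4 variant is used, one of several
  published forms;
* the positivity direction: ``lt`` indices flag BTT when the value falls
  strictly BELOW the threshold, ``gt`` indices when strictly ABOVE;
* an *original* threshold (the defining publication's cutoff) and a
  *present* threshold (the ROC/Youden-derived cutoff of the antenatal
  screening study this package reproduces).

Threshold comparisons are strict: a value exactly at the cutoff is negative.
This matches the "<" / ">" signs the source table prints, and is documented
so users can audit edge cases.

Known print artifacts in the source study, recorded here rather than
reproduced: its prose quotes a Mentzer sensitivity of 76.44% where its table
prints 76.74 (the table is taken as authoritative); its "Ricera" row is the
Ricerca index; and its MCH original-threshold row (sensitivity 36.2 at <27)
is internally inconsistent with an all-MCH<27 inclusion cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Callable, Literal, Mapping, Optional

from .records import CBCRecord

__all__ = [
    "IndexDefinition",
    "IndexValue",
    "INDEX_IDS",
    "registry",
    "compute_index",
    "compute_all",
    "flag_positive",
]

Direction = Literal["lt", "gt"]


@dataclass(frozen=True)
class IndexDefinition:
    """One discriminant index: identity, formula, direction, thresholds."""

    index_id: str
    display_name: str
    direction: Direction
    original_threshold: float
    present_threshold: float
    requires: frozenset[str]
    formula: Callable[[CBCRecord], float]

    def threshold(self, which: Literal["original", "present"]) -> float:
        if which == "original":
            return self.original_threshold
        if which == "present":
            return self.present_threshold
        raise ValueError(f"which must be 'original' or 'present', got {which!r}")


@dataclass(frozen=True)
class IndexValue:
    """A computed index value; ``computable`` is False iff an analyte is absent."""

    index_id: str
    value: Optional[float]
    computable: bool


def _def(index_id, name, direction, orig, present, requires, formula):
    return IndexDefinition(
        index_id=index_id, display_name=name, direction=direction,
        original_threshold=orig, present_threshold=present,
        requires=frozenset(requires), formula=formula,
    )


# Formulas with their defining citations:
#   Mentzer 1973 (Lancet):            MCV / RBC
#   RDWI, Jayabose 1999:              MCV * RDW / RBC
#   Shine & Lal 1977 (Lancet):        MCV^2 * MCH / 100
#   Srivastava 1973:                  MCH / RBC
#   Green & King 1989:                MCV^2 * RDW / (100 * Hb)
#   Sirdah 2007:                      MCV - RBC - 3*Hb
#   Ehsani 2009:                      MCV - 10*RBC
#   England & Fraser 1973 (Lancet):   MCV - RBC - 5*Hb - 3.4
#   Ricerca 1987:                     RDW / RBC
#   MDHL (Telmissani 1999):           MCH * RBC / MCV
#   MCHD (Telmissani 1999):           MCH / MCV
#   Sehgal 2015:                      MCV^2 / RBC
_DEFINITIONS = (
    _def("mentzer", "Mentzer", "lt", 13, 14.1,
         ("mcv", "rbc"), lambda r: r.mcv / r.rbc),
    _def("rdwi", "RDW index (RDWI)", "lt", 220, 255.9,
         ("mcv", "rdw", "rbc"), lambda r: r.mcv * r.rdw / r.rbc),
    _def("shine_lal", "Shine & Lal", "lt", 1530, 1142.41,
         ("mcv", "mch"), lambda r: r.mcv * r.mcv * r.mch / 100.0),
    _def("srivastava", "Srivastava", "lt", 3.8, 4.69,
         ("mch", "rbc"), lambda r: r.mch / r.rbc),
    _def("green_king", "Green & King", "lt", 65, 84.9,
         ("mcv", "rdw", "hb"), lambda r: r.mcv * r.mcv * r.rdw / (100.0 * r.hb)),
    _def("sirdah", "Sirdah", "lt", 27, 33.74,
         ("mcv", "rbc", "hb"), lambda r: r.mcv - r.rbc - 3.0 * r.hb),
    _def("ehsani", "Ehsani", "lt", 15, 20.1,
         ("mcv", "rbc"), lambda r: r.mcv - 10.0 * r.rbc),
    _def("england_fraser", "England & Fraser", "lt", 0, 10.98,
         ("mcv", "rbc", "hb"), lambda r: r.mcv - r.rbc - 5.0 * r.hb - 3.4),
    _def("ricerca", "Ricerca", "lt", 4.4, 3.65,
         ("rdw", "rbc"), lambda r: r.rdw / r.rbc),
    _def("mdhl", "Mean density of Hb/L (MDHL)", "gt", 1.63, 1.48,
         ("mch", "rbc", "mcv"), lambda r: r.mch * r.rbc / r.mcv),
    _def("mchd", "Mean cell Hb density (MCHD)", "gt", 0.3045, 0.3436,
         ("mch", "mcv"), lambda r: r.mch / r.mcv),
    _def("sehgal", "Sehgal", "lt", 972, 971.55,
         ("mcv", "rbc"), lambda r: r.mcv * r.mcv / r.rbc),
    _def("rbc_count", "RBC count", "gt", 4.81, 4.78,
         ("rbc",), lambda r: r.rbc),
    _def("mcv", "MCV", "lt", 80, 70.45,
         ("mcv",), lambda r: r.mcv),
    _def("mch", "MCH", "lt", 27, 23.7,
         ("mch",), lambda r: r.mch),
    _def("rdw", "RDW", "lt", 18, 17.35,
         ("rdw",), lambda r: r.rdw),
)

_REGISTRY: Mapping[str, IndexDefinition] = MappingProxyType(
    {d.index_id: d for d in _DEFINITIONS}
)

#: Index ids in canonical (source-table) order.
INDEX_IDS = tuple(d.index_id for d in _DEFINITIONS)


def registry() -> Mapping[str, IndexDefinition]:
    """Return the ordered, read-only mapping of all 16 index definitions."""
    return _REGISTRY


def _lookup(index_id: str) -> IndexDefinition:
    try:
        return _REGISTRY[index_id]
    except KeyError:
        raise KeyError(
            f"unknown index_id {index_id!r}; known: {', '.join(INDEX_IDS)}"
        ) from None


def compute_index(index_id: str, r: CBCRecord) -> IndexValue:
    """Evaluate one index on a record.

    Returns ``computable=False`` (and no value) when a required analyte is
    absent from the record, rather than guessing or substituting.
    """
    d = _lookup(index_id)
    if any(getattr(r, f, None) is None for f in d.requires):
        return IndexValue(index_id=index_id, value=None, computable=False)
    return IndexValue(index_id=index_id, value=float(d.formula(r)), computable=True)


def compute_all(r: CBCRecord) -> dict[str, IndexValue]:
    """Evaluate every registered index on one record, in registry order."""
    return {i: compute_index(i, r) for i in INDEX_IDS}


def flag_positive(
    index_id: str,
    v: IndexValue,
    which: Literal["original", "present"] = "present",
    reg: Mapping[str, IndexDefinition] | None = None,
) -> Optional[bool]:
    """Apply an index's threshold rule to a computed value.

    Strict comparison per the positivity direction: ``lt`` flags value <
    threshold, ``gt`` flags value > threshold; boundary equality is negative.
    A non-computable value propagates as ``None`` (never silently negative).
    """
    if v.index_id != index_id:
        raise ValueError(f"value is for {v.index_id!r}, not {index_id!r}")
    d = (reg or _REGISTRY)[index_id]
    if not v.computable or v.value is None:
        return None
    t = d.threshold(which)
    return v.value < t if d.direction == "lt" else v.value > t
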
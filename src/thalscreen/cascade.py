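"""Executable form of the antenatal beta-thalassemia screening cascade.

Stages, in order:

1. **CBC triage** — microcytic hypochromic anemia, strict thresholds
   MCV < 80 fL AND MCH < 27 pg AND Hb < 11 g/dL (configurable).
2. **Iron exclusion** — triaged subjects with an iron panel and transferrin
   saturation below the cutoff (default 16%, a standard clinical convention;
   optional serum-iron / TIBC conjuncts) are excluded as iron-deficiency
   anemia.
3. **HPLC classification** — HbA2 <= 3.5% is normal, >= 3.6% is
   beta-thalassemia trait; values in the open gap (3.5, 3.6) are equivocal
   and routed to genetic testing; a labeled non-A2 variant window overrides
   to "other hemoglobin variant".
4. **Analyzer flag audit** — the analyzer pop-up rule (default: Mentzer
   < 14.1 OR Sehgal < 971.55) is evaluated on every screened CBC and
   compared against the HPLC classifications.

Subjects lacking the data for a stage land in explicit "not assessed"
buckets; every subject reaches exactly one terminal disposition and the
bucket counts sum to the number screened.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

from .indices import compute_index, registry
from .records import CBCRecord, CohortTable, HPLCResult, IronPanel, SubjectRecord

__all__ = [
    "FlagRule",
    "CascadeConfig",
    "ScreeningSummary",
    "Disposition",
    "DEFAULT_FLAG_RULE",
    "is_microcytic_hypochromic",
    "iron_deficient",
    "classify_hplc",
    "analyzer_flag",
    "run_cascade",
    "missed_by_flag",
]

HPLCClass = Literal["normal", "btt", "other_variant", "equivocal"]

#: Terminal disposition buckets, in cascade order.
DISPOSITIONS = (
    "not_microcytic",
    "iron_deficient_excluded",
    "hplc_btt",
    "hplc_other_variant",
    "hplc_normal",
    "hplc_equivocal",
    "hplc_not_done",
)


@dataclass(frozen=True)
class FlagRule:
    """Analyzer pop-up rule: components combined by "any" (OR) or "all" (AND).

    Each component is ``(index_id, threshold, direction)`` with the strict
    comparison semantics of :mod:`thalscreen.indices`.
    """

    components: tuple[tuple[str, float, str], ...]
    combiner: Literal["any", "all"] = "any"

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("FlagRule needs at least one component")
        known = registry()
        for index_id, _, direction in self.components:
            if index_id not in known:
                raise ValueError(f"unknown index_id in flag rule: {index_id!r}")
            if direction not in ("lt", "gt"):
                raise ValueError(f"bad direction {direction!r} in flag rule")
        if self.combiner not in ("any", "all"):
            raise ValueError(f"combiner must be 'any' or 'all', got {self.combiner!r}")


#: Mentzer < 14.1 OR Sehgal < 971.55 (the study's derived cutoffs).
DEFAULT_FLAG_RULE = FlagRule(
    components=(("mentzer", 14.1, "lt"), ("sehgal", 971.55, "lt")),
    combiner="any",
)


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds for every cascade stage; defaults follow the model program."""

    mcv_max: float = 80.0       # fL, triage: MCV strictly below
    mch_max: float = 27.0       # pg, triage: MCH strictly below
    hb_max: float = 11.0        # g/dL, triage: Hb strictly below
    tsat_min: float = 16.0      # %, iron exclusion: TSAT strictly below
    serum_iron_min: Optional[float] = None  # ug/dL, optional conjunct
    tibc_max: Optional[float] = None        # ug/dL, optional conjunct
    hba2_normal_max: float = 3.5  # %, HbA2 at or below -> normal
    hba2_btt_min: float = 3.6     # %, HbA2 at or above -> trait
    flag_rule: FlagRule = DEFAULT_FLAG_RULE

    def __post_init__(self) -> None:
        if not self.hba2_normal_max < self.hba2_btt_min:
            raise ValueError("hba2_normal_max must be below hba2_btt_min")


@dataclass(frozen=True)
class Disposition:
    """Where one subject ended up, and whether the analyzer flag fired."""

    subject_id: str
    bucket: str
    flagged: Optional[bool]       # None when the rule was not computable
    hplc_class: Optional[HPLCClass] = None


@dataclass
class ScreeningSummary:
    """Counts at every cascade stage, plus derived percentages.

    ``prevalence_btt`` and ``spouse_uptake`` are full-precision percentages
    and are ``None`` when their denominator is zero.
    """

    n_screened: int = 0
    n_microcytic_hypochromic: int = 0
    n_iron_deficient_excluded: int = 0
    n_hplc_run: int = 0
    n_btt: int = 0
    n_other_variant: int = 0
    n_normal: int = 0
    n_equivocal: int = 0
    n_hplc_not_done: int = 0
    n_flagged: int = 0
    n_spouses_tested: int = 0
    bucket_counts: dict[str, int] = field(default_factory=dict)

    @property
    def prevalence_btt(self) -> Optional[float]:
        if self.n_hplc_run == 0:
            return None
        return 100.0 * self.n_btt / self.n_hplc_run

    @property
    def prevalence_other_variant(self) -> Optional[float]:
        if self.n_hplc_run == 0:
            return None
        return 100.0 * self.n_other_variant / self.n_hplc_run

    @property
    def fraction_normal(self) -> Optional[float]:
        if self.n_hplc_run == 0:
            return None
        return 100.0 * self.n_normal / self.n_hplc_run

    @property
    def spouse_uptake(self) -> Optional[float]:
        if self.n_btt == 0:
            return None
        return 100.0 * self.n_spouses_tested / self.n_btt

    def as_dict(self) -> dict:
        return {
            "n_screened": self.n_screened,
            "n_microcytic_hypochromic": self.n_microcytic_hypochromic,
            "n_iron_deficient_excluded": self.n_iron_deficient_excluded,
            "n_hplc_run": self.n_hplc_run,
            "n_btt": self.n_btt,
            "n_other_variant": self.n_other_variant,
            "n_normal": self.n_normal,
            "n_equivocal": self.n_equivocal,
            "n_hplc_not_done": self.n_hplc_not_done,
            "n_flagged": self.n_flagged,
            "n_spouses_tested": self.n_spouses_tested,
            "prevalence_btt": self.prevalence_btt,
            "prevalence_other_variant": self.prevalence_other_variant,
            "fraction_normal": self.fraction_normal,
            "spouse_uptake": self.spouse_uptake,
            "bucket_counts": dict(self.bucket_counts),
        }


def is_microcytic_hypochromic(r: CBCRecord, cfg: CascadeConfig = CascadeConfig()) -> bool:
    """Triage rule: MCV, MCH and Hb all strictly below their cutoffs."""
    return r.mcv < cfg.mcv_max and r.mch < cfg.mch_max and r.hb < cfg.hb_max


def iron_deficient(p: IronPanel, cfg: CascadeConfig = CascadeConfig()) -> bool:
    """Iron-deficiency call: TSAT strictly below cutoff, optional conjuncts."""
    deficient = p.tsat < cfg.tsat_min
    if cfg.serum_iron_min is not None:
        deficient = deficient and p.serum_iron < cfg.serum_iron_min
    if cfg.tibc_max is not None:
        deficient = deficient and p.tibc > cfg.tibc_max
    return deficient


def classify_hplc(h: HPLCResult, cfg: CascadeConfig = CascadeConfig()) -> HPLCClass:
    """HPLC decision rule on the HbA2 fraction.

    A labeled non-A2 variant window takes precedence; otherwise HbA2 at or
    below 3.5% is normal, at or above 3.6% is beta-thalassemia trait, and
    the open gap between the two bounds is equivocal.
    """
    if h.variant_window:
        return "other_variant"
    if h.hba2 <= cfg.hba2_normal_max:
        return "normal"
    if h.hba2 >= cfg.hba2_btt_min:
        return "btt"
    return "equivocal"


def analyzer_flag(
    r: CBCRecord, rule: FlagRule = DEFAULT_FLAG_RULE
) -> tuple[Optional[bool], tuple[str, ...]]:
    """Evaluate the analyzer pop-up rule on one CBC.

    Returns ``(flagged, contributing_index_ids)``.  Components whose index
    cannot be computed (missing analyte) are dropped from an "any" rule; if
    no component is computable the result is ``(None, ())`` — a
    not-computable marker, never a silent negative.  An "all" rule with any
    non-computable component is likewise not computable.
    """
    fired: list[str] = []
    outcomes: list[bool] = []
    any_non_computable = False
    for index_id, threshold, direction in rule.components:
        iv = compute_index(index_id, r)
        if not iv.computable:
            any_non_computable = True
            continue
        hit = iv.value < threshold if direction == "lt" else iv.value > threshold
        outcomes.append(hit)
        if hit:
            fired.append(index_id)
    if rule.combiner == "any":
        if not outcomes:
            return None, ()
        return bool(any(outcomes)), tuple(fired)
    if any_non_computable:
        return None, ()
    return bool(all(outcomes)), tuple(fired)


def run_cascade(
    cohort: CohortTable, cfg: CascadeConfig = CascadeConfig()
) -> tuple[ScreeningSummary, list[Disposition]]:
    """Run the full screening cascade over a cohort.

    Every subject reaches exactly one terminal bucket; spouse-testing uptake
    is accounted over HPLC-confirmed carriers with a recorded spouse_tested
    field.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    summary = ScreeningSummary(bucket_counts={b: 0 for b in DISPOSITIONS})
    dispositions: list[Disposition] = []

    for rec in cohort:
        summary.n_screened += 1
        flagged, _ = analyzer_flag(rec.cbc, cfg.flag_rule)
        if flagged:
            summary.n_flagged += 1

        if not is_microcytic_hypochromic(rec.cbc, cfg):
            bucket, hplc_class = "not_microcytic", None
        elif rec.iron is not None and iron_deficient(rec.iron, cfg):
            summary.n_microcytic_hypochromic += 1
            summary.n_iron_deficient_excluded += 1
            bucket, hplc_class = "iron_deficient_excluded", None
        elif rec.hplc is None:
            summary.n_microcytic_hypochromic += 1
            summary.n_hplc_not_done += 1
            bucket, hplc_class = "hplc_not_done", None
        else:
            summary.n_microcytic_hypochromic += 1
            summary.n_hplc_run += 1
            hplc_class = classify_hplc(rec.hplc, cfg)
            bucket = f"hplc_{hplc_class}"
            if hplc_class == "btt":
                summary.n_btt += 1
                if rec.spouse_tested:
                    summary.n_spouses_tested += 1
            elif hplc_class == "other_variant":
                summary.n_other_variant += 1
            elif hplc_class == "normal":
                summary.n_normal += 1
            else:
                summary.n_equivocal += 1

        summary.bucket_counts[bucket] += 1
        dispositions.append(
            Disposition(
                subject_id=rec.subject_id, bucket=bucket,
                flagged=flagged, hplc_class=hplc_class,
            )
        )
    return summary, dispositions


def missed_by_flag(
    cohort: CohortTable, cfg: CascadeConfig = CascadeConfig()
) -> list[str]:
    """Subject ids HPLC-classified as carriers but NOT raised by the flag rule.

    The audit the analyzer pop-up exists to make empty: carriers the rule
    would have let through to routine reporting.
    """
    missed: list[str] = []
    for rec in cohort:
        if rec.hplc is None or classify_hplc(rec.hplc, cfg) != "btt":
            continue
        flagged, _ = analyzer_flag(rec.cbc, cfg.flag_rule)
        if flagged is not True:
            missed.append(rec.subject_id)
    return missed


def with_flag_rule(cfg: CascadeConfig, rule: FlagRule) -> CascadeConfig:
    return replace(cfg, flag_rule=rule)
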
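"""Index-performance reporting: one row per discriminant index.

For a labeled cohort the report gives, per index, sensitivity/specificity at
the published (original) cutoff, the Youden-derived cutoff on this cohort
with its sensitivity/specificity, and the AUC — the layout of the
comparison tables screening studies print.

Class conventions follow the study design: the positive class is HPLC-
confirmed beta-thalassemia trait and the negative class is HPLC-normal
subjects only; other-variant carriers and iron-deficient subjects are not
in either denominator.  Subjects missing an analyte an index requires are
excluded from that index's denominators (and counted), so missing RDW can
never bias an RDW-free index.

The report keeps exact fractions (tp/n) alongside rounded percentages, so
rounding-versus-truncation ambiguities in printed tables cannot arise in
this package's own output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from . import roc as roc_stats
from .indices import INDEX_IDS, compute_index, registry
from .records import CohortTable

__all__ = ["IndexPerformanceRow", "table1_report", "report_frame"]


@dataclass(frozen=True)
class IndexPerformanceRow:
    """Performance of one index on a labeled cohort at both cutoffs."""

    index_id: str
    display_name: str
    direction: str
    evaluable: bool
    n_pos: int = 0
    n_neg: int = 0
    n_excluded: int = 0  # labeled subjects missing a required analyte
    threshold_original: Optional[float] = None
    sens_original: Optional[float] = None
    spec_original: Optional[float] = None
    tp_original: Optional[int] = None
    tn_original: Optional[int] = None
    threshold_derived: Optional[float] = None
    sens_derived: Optional[float] = None
    spec_derived: Optional[float] = None
    tp_derived: Optional[int] = None
    tn_derived: Optional[int] = None
    auc: Optional[float] = None


def _labeled_values(cohort: CohortTable, index_id: str):
    """(values, labels, n_excluded) for btt-vs-normal evaluation of one index."""
    values, labels, excluded = [], [], 0
    for rec in cohort:
        if rec.true_class not in ("btt", "normal"):
            continue
        iv = compute_index(index_id, rec.cbc)
        if not iv.computable:
            excluded += 1
            continue
        values.append(iv.value)
        labels.append(rec.true_class == "btt")
    return values, labels, excluded


def table1_report(cohort: CohortTable) -> list[IndexPerformanceRow]:
    """Evaluate all 16 indices on a labeled cohort, in registry order.

    An index whose required analytes leave either class empty is marked
    non-evaluable; the other rows are unaffected.
    """
    reg = registry()
    rows: list[IndexPerformanceRow] = []
    for index_id in INDEX_IDS:
        d = reg[index_id]
        values, labels, excluded = _labeled_values(cohort, index_id)
        n_pos = sum(labels)
        n_neg = len(labels) - n_pos
        if n_pos == 0 or n_neg == 0:
            rows.append(
                IndexPerformanceRow(
                    index_id=index_id, display_name=d.display_name,
                    direction=d.direction, evaluable=False,
                    n_pos=n_pos, n_neg=n_neg, n_excluded=excluded,
                )
            )
            continue
        c_orig = roc_stats.confusion(values, labels, d.original_threshold, d.direction)
        sens_o, spec_o = roc_stats.metrics(c_orig)
        curve = roc_stats.empirical_roc(values, labels, d.direction, index_id=index_id)
        cut = roc_stats.youden_optimal(curve, reference_threshold=d.original_threshold)
        c_der = roc_stats.confusion(values, labels, cut.threshold, d.direction)
        sens_d, spec_d = roc_stats.metrics(c_der)
        rows.append(
            IndexPerformanceRow(
                index_id=index_id, display_name=d.display_name,
                direction=d.direction, evaluable=True,
                n_pos=n_pos, n_neg=n_neg, n_excluded=excluded,
                threshold_original=d.original_threshold,
                sens_original=sens_o, spec_original=spec_o,
                tp_original=c_orig.tp, tn_original=c_orig.tn,
                threshold_derived=cut.threshold,
                sens_derived=sens_d, spec_derived=spec_d,
                tp_derived=c_der.tp, tn_derived=c_der.tn,
                auc=roc_stats.auc(curve),
            )
        )
    return rows


def report_frame(rows: list[IndexPerformanceRow]) -> pd.DataFrame:
    """Tabulate report rows: exact fractions plus 2-dp rounded percentages."""
    out = []
    for r in rows:
        rec = {
            "index_id": r.index_id,
            "display_name": r.display_name,
            "direction": r.direction,
            "evaluable": r.evaluable,
            "n_pos": r.n_pos,
            "n_neg": r.n_neg,
            "n_excluded": r.n_excluded,
        }
        if r.evaluable:
            rec.update({
                "threshold_original": r.threshold_original,
                "sens_original_frac": f"{r.tp_original}/{r.n_pos}",
                "sens_original": roc_stats.round_half_away(r.sens_original, 2),
                "spec_original_frac": f"{r.tn_original}/{r.n_neg}",
                "spec_original": roc_stats.round_half_away(r.spec_original, 2),
                "threshold_derived": r.threshold_derived,
                "sens_derived_frac": f"{r.tp_derived}/{r.n_pos}",
                "sens_derived": roc_stats.round_half_away(r.sens_derived, 2),
                "spec_derived_frac": f"{r.tn_derived}/{r.n_neg}",
                "spec_derived": roc_stats.round_half_away(r.spec_derived, 2),
                "auc": round(r.auc, 4),
            })
        out.append(rec)
    return pd.DataFrame(out)
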
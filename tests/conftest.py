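"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately written as plain Python loops, separate
from the vectorised implementation they check.
"""

from __future__ import annotations

import pytest

from thalscreen.records import (
    CBCRecord,
    CohortTable,
    HPLCResult,
    IronPanel,
    SubjectRecord,
)


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_confusion(values, labels, threshold, direction):
    """Exhaustive per-subject confusion counting (oracle)."""
    tp = fp = tn = fn = 0
    for v, y in zip(values, labels):
        flagged = v < threshold if direction == "lt" else v > threshold
        if flagged and y:
            tp += 1
        elif flagged and not y:
            fp += 1
        elif not flagged and y:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def brute_roc_points(values, labels, direction):
    """Exhaustive threshold sweep: midpoints between sorted distinct values
    plus infinite sentinels, confusion counted subject by subject."""
    distinct = sorted(set(values))
    thresholds = [float("-inf")]
    for a, b in zip(distinct, distinct[1:]):
        thresholds.append((a + b) / 2)
    thresholds.append(float("inf"))
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    points = []
    for t in thresholds:
        tp, fp, tn, fn = brute_confusion(values, labels, t, direction)
        points.append((t, 100.0 * tp / n_pos, 100.0 * tn / n_neg))
    return points


def brute_auc(values, labels, direction):
    """Pairwise concordance probability, ties counted one half (oracle)."""
    pos = [v for v, y in zip(values, labels) if y]
    neg = [v for v, y in zip(values, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            if direction == "lt":
                total += 1.0 if p < n else (0.5 if p == n else 0.0)
            else:
                total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# hand-built cohorts


def _subject(sid, hb, rbc, mcv, mch, rdw=None, iron=None, hplc=None,
             true_class=None, spouse=None):
    return SubjectRecord(
        cbc=CBCRecord(subject_id=sid, hb=hb, rbc=rbc, mcv=mcv, mch=mch, rdw=rdw),
        iron=iron, hplc=hplc, true_class=true_class, spouse_tested=spouse,
    )


@pytest.fixture
def six_subject_cohort() -> CohortTable:
    """Six labeled subjects: three carriers (high RBC, low MCV), three
    HPLC-normal, all analytes present. Small enough to hand-trace."""
    return CohortTable(records=[
        _subject("P1", 8.9, 5.21, 65.12, 20.86, rdw=15.0,
                 hplc=HPLCResult(4.8), true_class="btt"),
        _subject("P2", 9.5, 5.50, 62.0, 19.5, rdw=14.2,
                 hplc=HPLCResult(5.2), true_class="btt"),
        _subject("P3", 10.1, 4.90, 68.0, 22.0, rdw=15.8,
                 hplc=HPLCResult(4.1), true_class="btt"),
        _subject("N1", 10.4, 4.10, 76.0, 24.5, rdw=13.5,
                 hplc=HPLCResult(2.6), true_class="normal"),
        _subject("N2", 10.0, 4.40, 73.0, 23.8, rdw=14.0,
                 hplc=HPLCResult(2.9), true_class="normal"),
        _subject("N3", 10.7, 4.00, 78.5, 25.9, rdw=13.0,
                 hplc=HPLCResult(3.1), true_class="normal"),
    ], provenance="fixture")


@pytest.fixture
def ten_record_cascade_cohort() -> CohortTable:
    """Hand-traced cascade fixture: 3 non-microcytic, 2 iron-deficient,
    5 HPLC (2 btt / 1 other variant / 2 normal)."""
    replete = IronPanel(serum_iron=90, tibc=320)   # tsat 28.1%
    deficient = IronPanel(serum_iron=20, tibc=450)  # tsat 4.4%
    return CohortTable(records=[
        # fails triage: MCV and Hb too high
        _subject("A1", 12.5, 4.6, 88.0, 29.0),
        _subject("A2", 13.0, 4.8, 92.0, 30.0),
        _subject("A3", 11.8, 4.5, 85.0, 28.0),
        # microcytic, iron deficient -> excluded
        _subject("B1", 9.0, 3.8, 70.0, 21.0, iron=deficient),
        _subject("B2", 8.5, 3.6, 68.0, 20.0, iron=deficient),
        # microcytic, iron replete, HPLC done
        _subject("C1", 8.9, 5.21, 65.12, 20.86, iron=replete,
                 hplc=HPLCResult(4.8), true_class="btt", spouse=True),
        _subject("C2", 9.4, 5.4, 63.0, 19.9, iron=replete,
                 hplc=HPLCResult(5.5), true_class="btt", spouse=False),
        _subject("C3", 9.8, 4.5, 71.0, 22.5, iron=replete,
                 hplc=HPLCResult(2.4, variant_window="S-window"),
                 true_class="other_variant"),
        _subject("C4", 10.2, 4.2, 74.0, 24.0, iron=replete,
                 hplc=HPLCResult(2.8), true_class="normal"),
        _subject("C5", 10.5, 4.3, 75.0, 24.5, iron=replete,
                 hplc=HPLCResult(3.2), true_class="normal"),
    ], provenance="fixture")
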
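"""Empirical ROC construction, AUC, Youden-optimal cutoffs and printed-table
fraction utilities, written from scratch.

Conventions
-----------
``labels`` mark the disease-positive class (carriers); ``direction`` follows
:mod:`thalscreen.indices`: an ``lt`` marker flags positive strictly below a
threshold, a ``gt`` marker strictly above.  Sensitivity and specificity are
percentages; AUC is a fraction in [0, 1] computed by trapezoidal integration
over (1 - specificity, sensitivity), which for the midpoint-threshold curve
equals the rank (concordance) statistic with ties counted one half.

Candidate thresholds are the midpoints between consecutive distinct observed
values, plus -inf/+inf sentinels, so the curve is reproducible and does not
depend on instrument resolution.

Percentages are rounded half-away-from-zero.  Published screening tables mix
rounding and truncation at 1-5 decimals; :func:`reconstruct_count` therefore
accepts a count as consistent with a printed percentage if either convention
reproduces it at the printed precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "RocPoint",
    "RocCurve",
    "OptimalCut",
    "AMBIGUOUS",
    "confusion",
    "metrics",
    "empirical_roc",
    "auc",
    "youden_optimal",
    "reconstruct_count",
    "round_half_away",
]

Direction = Literal["lt", "gt"]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 table of a threshold rule against the reference standard."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float  # percent
    specificity: float  # percent


@dataclass(frozen=True)
class RocCurve:
    """Empirical operating points of one marker on a labeled cohort."""

    index_id: str
    direction: Direction
    points: tuple[RocPoint, ...]
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class OptimalCut:
    """A Youden-maximal operating point; youden_j = sens + spec - 100."""

    threshold: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 100.0


class _Ambiguous:
    def __repr__(self) -> str:  # pragma: no cover - repr only
        return "AMBIGUOUS"


#: Sentinel returned by :func:`reconstruct_count` when several counts match.
AMBIGUOUS = _Ambiguous()


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (12.345 -> 12.35), unlike banker's rounding."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def _positive_mask(values: np.ndarray, threshold: float, direction: Direction):
    if direction == "lt":
        return values < threshold
    if direction == "gt":
        return values > threshold
    raise ValueError(f"direction must be 'lt' or 'gt', got {direction!r}")


def confusion(
    values: Sequence[float],
    labels: Sequence[bool],
    threshold: float,
    direction: Direction,
) -> ConfusionCounts:
    """Count the 2x2 table for a strict threshold rule.

    ``values`` and ``labels`` are per-subject and equal length; a subject
    counts as test-positive when its value is strictly on the flag side of
    the threshold.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-d sequences")
    if v.size == 0:
        raise ValueError("empty cohort")
    flagged = _positive_mask(v, threshold, direction)
    return ConfusionCounts(
        tp=int(np.sum(flagged & y)),
        fp=int(np.sum(flagged & ~y)),
        tn=int(np.sum(~flagged & ~y)),
        fn=int(np.sum(~flagged & y)),
    )


def metrics(c: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity %, specificity %) at full precision.

    Raises on an empty class, naming it; use :func:`round_half_away` for
    presentation rounding.
    """
    if c.n_pos == 0:
        raise ValueError("no disease-positive subjects: sensitivity undefined")
    if c.n_neg == 0:
        raise ValueError("no disease-negative subjects: specificity undefined")
    return 100.0 * c.tp / c.n_pos, 100.0 * c.tn / c.n_neg


def empirical_roc(
    values: Sequence[float],
    labels: Sequence[bool],
    direction: Direction,
    index_id: str = "",
) -> RocCurve:
    """Build the empirical ROC curve of a continuous marker.

    One operating point per candidate threshold: midpoints between
    consecutive distinct observed values plus -inf/+inf sentinels.  The
    result is equivalent, point for point, to evaluating :func:`confusion`
    at every candidate threshold.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-d sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty to build a ROC curve")

    distinct = np.unique(v)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))

    # Vectorised sweep: counts of positives/negatives strictly below each
    # threshold, via cumulative class counts over the sorted values.
    order = np.argsort(v, kind="stable")
    sorted_y = y[order]
    sorted_v = v[order]
    cum_pos = np.concatenate(([0], np.cumsum(sorted_y)))
    cum_neg = np.concatenate(([0], np.cumsum(~sorted_y)))
    below = np.searchsorted(sorted_v, thresholds, side="left")
    pos_below = cum_pos[below]
    neg_below = cum_neg[below]

    if direction == "lt":
        tp, fp = pos_below, neg_below
    elif direction == "gt":
        tp, fp = n_pos - pos_below, n_neg - neg_below
    else:
        raise ValueError(f"direction must be 'lt' or 'gt', got {direction!r}")

    points = tuple(
        RocPoint(
            threshold=float(t),
            sensitivity=100.0 * tp_i / n_pos,
            specificity=100.0 * (n_neg - fp_i) / n_neg,
        )
        for t, tp_i, fp_i in zip(thresholds, tp, fp)
    )
    return RocCurve(
        index_id=index_id, direction=direction, points=points,
        n_pos=n_pos, n_neg=n_neg,
    )


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve, as a fraction in [0, 1].

    With midpoint thresholds this equals the concordance probability
    P(marker orders a random positive/negative pair correctly), ties
    counted one half.
    """
    fpr = np.array([(100.0 - p.specificity) / 100.0 for p in curve.points])
    tpr = np.array([p.sensitivity / 100.0 for p in curve.points])
    # lexical sort keeps vertical segments (equal fpr) in path order
    order = np.lexsort((tpr, fpr))
    return float(abs(np.trapezoid(tpr[order], fpr[order])))


def youden_optimal(
    curve: RocCurve, reference_threshold: Optional[float] = None
) -> OptimalCut:
    """Operating point maximizing Youden J = sensitivity + specificity - 100.

    Ties are broken by higher sensitivity, then (when a published reference
    cutoff is supplied) by threshold closest to it, then by lower threshold,
    so the result is deterministic.
    """
    if not curve.points:
        raise ValueError("empty ROC curve")

    def sort_key(p: RocPoint):
        j = p.sensitivity + p.specificity
        dist = (
            abs(p.threshold - reference_threshold)
            if reference_threshold is not None and math.isfinite(p.threshold)
            else math.inf
        )
        return (-j, -p.sensitivity, dist, p.threshold)

    best = min(curve.points, key=sort_key)
    return OptimalCut(
        threshold=best.threshold,
        sensitivity=best.sensitivity,
        specificity=best.specificity,
    )


def _truncate(x: float, decimals: int) -> float:
    factor = 10.0 ** decimals
    return math.floor(x * factor + 1e-9) / factor


def reconstruct_count(
    percent: float, denominator: int, decimals: int = 2
):
    """Invert a printed percentage back to its integer numerator.

    Returns the unique k in [0, denominator] whose percentage, printed at
    ``decimals`` places by either half-away-from-zero rounding or
    truncation, equals ``percent``; ``None`` if no k matches;
    :data:`AMBIGUOUS` if several do.  Accepting both print conventions
    reflects how published tables actually mix them.
    """
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if not 0 <= percent <= 100:
        raise ValueError("percent must lie in [0, 100]")
    tol = 10.0 ** (-decimals) / 100.0
    matches = []
    for k in range(denominator + 1):
        p = 100.0 * k / denominator
        if (
            abs(round_half_away(p, decimals) - percent) < tol
            or abs(_truncate(p, decimals) - percent) < tol
        ):
            matches.append(k)
    if not matches:
        return None
    if len(matches) > 1:
        return AMBIGUOUS
    return matches[0]
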
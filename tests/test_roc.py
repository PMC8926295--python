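"""ROC construction, AUC, Youden cutoffs and printed-fraction utilities."""

import math

import numpy as np
import pytest

from conftest import brute_auc, brute_confusion, brute_roc_points
from thalscreen.roc import (
    AMBIGUOUS,
    ConfusionCounts,
    auc,
    confusion,
    empirical_roc,
    metrics,
    reconstruct_count,
    round_half_away,
    youden_optimal,
)


class TestConfusion:
    def test_two_subject_example(self):
        c = confusion([12, 16], [True, False], 14.1, "lt")
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 1, 0)

    def test_all_positive_cohort_has_no_negatives(self):
        c = confusion([1, 2, 3], [True, True, True], 2.5, "lt")
        assert c.fp == 0 and c.tn == 0
        assert c.tp + c.fn == 3

    def test_six_subject_fixture_matches_brute_force(self):
        values = [12.0, 13.5, 14.1, 14.1, 15.9, 20.0]
        labels = [True, True, True, False, False, False]
        for thr in [11, 13.7, 14.1, 14.2, 25]:
            for direction in ("lt", "gt"):
                c = confusion(values, labels, thr, direction)
                assert (c.tp, c.fp, c.tn, c.fn) == brute_confusion(
                    values, labels, thr, direction
                )

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion([], [], 1.0, "lt")


class TestMetrics:
    def test_carrier_series_fractions(self):
        # 42/43 and 102/116
        sens, spec = metrics(ConfusionCounts(tp=42, fp=14, tn=102, fn=1))
        assert round_half_away(sens, 2) == 97.67
        assert round_half_away(spec, 2) == 87.93

    def test_shine_lal_style_fractions(self):
        # 41/43 rounds to 95.35 (a table printing 95.34 truncated)
        sens, spec = metrics(ConfusionCounts(tp=41, fp=39, tn=77, fn=2))
        assert round_half_away(sens, 2) == 95.35
        assert round_half_away(spec, 2) == 66.38

    def test_degenerate_all_negative_test(self):
        sens, spec = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert (sens, spec) == (0.0, 100.0)

    @pytest.mark.parametrize(
        "counts, missing",
        [(ConfusionCounts(0, 3, 4, 0), "positive"),
         (ConfusionCounts(3, 0, 0, 1), "negative")],
    )
    def test_zero_denominator_names_the_class(self, counts, missing):
        with pytest.raises(ValueError, match=missing):
            metrics(counts)


class TestEmpiricalRoc:
    def test_perfect_separation_reaches_corner(self):
        curve = empirical_roc([1, 2, 3, 4], [True, True, False, False], "lt")
        assert any(p.sensitivity == 100 and p.specificity == 100
                   for p in curve.points)

    def test_endpoints_present(self):
        curve = empirical_roc([1, 2, 3], [True, False, True], "lt")
        ops = {(p.sensitivity, p.specificity) for p in curve.points}
        assert (0.0, 100.0) in ops and (100.0, 0.0) in ops

    def test_identical_distributions_auc_half(self):
        values = [1, 2, 3, 1, 2, 3]
        labels = [True, True, True, False, False, False]
        assert auc(empirical_roc(values, labels, "lt")) == pytest.approx(0.5)

    def test_eight_value_fixture_matches_exhaustive_sweep(self):
        values = [3.0, 1.5, 2.5, 4.0, 2.5, 5.0, 0.5, 3.5]
        labels = [True, True, True, False, False, False, True, False]
        for direction in ("lt", "gt"):
            curve = empirical_roc(values, labels, direction)
            expected = brute_roc_points(values, labels, direction)
            assert len(curve.points) == len(expected)
            for p, (t, sens, spec) in zip(curve.points, expected):
                assert p.threshold == t
                assert p.sensitivity == pytest.approx(sens)
                assert p.specificity == pytest.approx(spec)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            empirical_roc([1, 2], [True, True], "lt")


class TestAuc:
    def test_perfect_separation(self):
        assert auc(empirical_roc([1, 2, 3, 4], [True, True, False, False],
                                 "lt")) == pytest.approx(1.0)

    def test_interleaved_pairs(self):
        # pos {1,3}, neg {2,4}, lt-positive: of 4 pairs, 3 concordant
        curve = empirical_roc([1, 3, 2, 4], [True, True, False, False], "lt")
        assert auc(curve) == pytest.approx(0.75)

    def test_trapezoid_equals_concordance_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = rng.integers(4, 30)
            values = rng.integers(0, 8, size=n).astype(float)  # force ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            for direction in ("lt", "gt"):
                curve = empirical_roc(values, labels, direction)
                assert auc(curve) == pytest.approx(
                    brute_auc(values, labels, direction), abs=1e-12
                )

    def test_matches_reference_roc_implementation(self):
        """Independent cross-check against scikit-learn's rank-based AUC."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(6, 60))
            values = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.random(n) < 0.5
            labels[0], labels[-1] = True, False
            ours = auc(empirical_roc(values, labels, "lt"))
            reference = roc_auc_score(labels, -values)
            assert ours == pytest.approx(reference, abs=1e-12)

    def test_label_flip_maps_auc_to_complement(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        a = auc(empirical_roc(values, labels, "lt"))
        b = auc(empirical_roc(values, ~labels, "lt"))
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestYoudenOptimal:
    def test_perfect_separation_j_100(self):
        cut = youden_optimal(
            empirical_roc([1, 2, 3, 4], [True, True, False, False], "lt")
        )
        assert cut.youden_j == pytest.approx(100.0)
        assert 2 < cut.threshold < 3

    def test_identical_distributions_j_zero(self):
        curve = empirical_roc([1, 2, 1, 2], [True, True, False, False], "lt")
        assert youden_optimal(curve).youden_j == pytest.approx(0.0)

    def test_eight_value_fixture_argmax_by_brute_force(self):
        values = [3.0, 1.5, 2.5, 4.0, 2.5, 5.0, 0.5, 3.5]
        labels = [True, True, True, False, False, False, True, False]
        curve = empirical_roc(values, labels, "lt")
        cut = youden_optimal(curve)
        best_j = max(sens + spec - 100 for _, sens, spec
                     in brute_roc_points(values, labels, "lt"))
        assert cut.youden_j == pytest.approx(best_j)

    def test_tie_break_prefers_higher_sensitivity(self):
        # both midpoints reach J=50; the higher-sensitivity one must win
        values = [1.0, 2.0, 3.0, 4.0]
        labels = [True, False, True, False]
        cut = youden_optimal(empirical_roc(values, labels, "lt"))
        assert cut.sensitivity == 100.0

    def test_reference_threshold_keeps_result_deterministic(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        labels = [True, True, True, False, False, False]
        curve = empirical_roc(values, labels, "lt")
        with_ref = youden_optimal(curve, reference_threshold=3.0)
        without = youden_optimal(curve)
        assert with_ref.youden_j == without.youden_j == pytest.approx(100.0)


class TestReconstructCount:
    def test_normal_fraction_of_183(self):
        assert reconstruct_count(63.4, 183, 1) == 116

    def test_sensitivity_fraction_of_43(self):
        assert reconstruct_count(97.67, 43, 2) == 42

    def test_no_candidate(self):
        assert reconstruct_count(50.0, 3, 1) is None

    def test_ambiguous_when_coarse(self):
        # at 0 decimals over 1000, many k print as "50"
        assert reconstruct_count(50.0, 1000, 0) is AMBIGUOUS

    def test_truncated_print_convention_accepted(self):
        # 42/43 = 97.674...; a table printing 97.6 truncated still inverts
        assert reconstruct_count(97.6, 43, 1) == 42

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_count(101, 43, 2)
        with pytest.raises(ValueError):
            reconstruct_count(50, 0, 2)


def test_round_half_away_from_zero():
    assert round_half_away(82.755, 2) == 82.76
    assert round_half_away(2.5, 0) == 3.0
    assert round_half_away(-2.5, 0) == -3.0
    assert math.isclose(round_half_away(97.6744, 2), 97.67)
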
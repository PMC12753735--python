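"""Evaluation metric tests, including the Dice-IoU identity and the
pair-counting AUC oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import auc_pair_counting
from smearkit.evaluation import (
    BinaryMetrics,
    ConfusionCounts,
    aggregate_folds,
    binary_metrics,
    confusion_matrix,
    multiclass_report,
    overlap_metrics,
    roc_auc,
)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.arange(9)
        cm = confusion_matrix(y, y)
        assert np.array_equal(cm, np.eye(9, dtype=int))

    def test_rows_are_actual_columns_predicted(self):
        # every Basophil (class 3) predicted as Eosinophil (class 4)
        y_true = np.array([3, 3, 3])
        y_pred = np.array([4, 4, 4])
        cm = confusion_matrix(y_true, y_pred)
        assert cm[3, 4] == 3
        assert cm.sum() == 3

    def test_total_equals_sample_count(self, rng):
        y = rng.integers(0, 9, 100)
        p = rng.integers(0, 9, 100)
        assert confusion_matrix(y, p).sum() == 100

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 9], [0, 0])


class TestBinaryMetrics:
    def test_perfect_counts(self):
        m = binary_metrics(ConfusionCounts(5, 5, 0, 0))
        assert m.accuracy == 1.0 and m.f1 == 1.0 and not m.undefined

    def test_direct_arithmetic(self):
        m = binary_metrics(ConfusionCounts(tp=3, tn=0, fp=1, fn=3))
        assert m.precision == 0.75
        assert m.recall == 0.5

    def test_f1_is_harmonic_mean(self):
        # precision 0.8, recall 0.6 -> F1 = 2*0.48/1.4
        m = binary_metrics(ConfusionCounts(tp=12, tn=0, fp=3, fn=8))
        assert m.precision == pytest.approx(0.8)
        assert m.recall == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 * 0.48 / 1.4)

    def test_zero_denominator_reported_as_undefined_not_zero(self):
        m = binary_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert m.precision is None
        assert "precision" in m.undefined

    @given(tp=st.integers(0, 50), tn=st.integers(0, 50),
           fp=st.integers(0, 50), fn=st.integers(0, 50))
    @settings(max_examples=200, deadline=None)
    def test_f1_between_precision_and_recall(self, tp, tn, fp, fn):
        m = binary_metrics(ConfusionCounts(tp, tn, fp, fn))
        if m.f1 is not None:
            assert min(m.precision, m.recall) - 1e-12 <= m.f1 <= max(m.precision, m.recall) + 1e-12


class TestOverlapMetrics:
    def test_identical_masks(self, rng):
        m = rng.random((8, 8)) > 0.5
        assert overlap_metrics(m, m) == (1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = b[3, 3] = True
        assert overlap_metrics(a, b) == (0.0, 0.0)

    def test_half_overlap_counts(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, :4] = True
        b[0, 2:] = b[1, :2] = True
        # |A| = |B| = 4, |inter| = 2
        iou, dice = overlap_metrics(a, b)
        assert iou == pytest.approx(1 / 3)
        assert dice == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((3, 3), bool)
        assert overlap_metrics(z, z) == (1.0, 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlap_metrics(np.zeros((2, 2)), np.zeros((3, 3)))

    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    @settings(max_examples=300, deadline=None)
    def test_dice_iou_identity_to_1e12(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(16)], bool).reshape(4, 4)
        b = np.array([(bits_b >> i) & 1 for i in range(16)], bool).reshape(4, 4)
        iou, dice = overlap_metrics(a, b)
        assert abs(dice - 2 * iou / (1 + iou)) < 1e-12


class TestRocAuc:
    def test_perfectly_separable_scores(self):
        y = np.array([1, 1, 0, 0])
        p = np.column_stack([1 - np.array([0.9, 0.8, 0.3, 0.1]),
                             [0.9, 0.8, 0.3, 0.1]])
        out = roc_auc(y, p)
        assert out["per_class"][1] == pytest.approx(1.0)

    def test_label_independent_scores_give_half(self):
        y = np.array([0, 1, 0, 1])
        p = np.full((4, 2), 0.5)
        out = roc_auc(y, p)
        assert out["per_class"][0] == pytest.approx(0.5)
        assert out["per_class"][1] == pytest.approx(0.5)

    def test_four_sample_toy_matches_enumerated_pairs(self):
        scores = np.array([0.9, 0.8, 0.3, 0.1])
        y = np.array([1, 1, 0, 0])
        p = np.column_stack([1 - scores, scores])
        assert roc_auc(y, p)["per_class"][1] == pytest.approx(1.0)
        swapped = np.array([0.9, 0.3, 0.8, 0.1])  # one positive-negative swap
        p2 = np.column_stack([1 - swapped, swapped])
        assert roc_auc(y, p2)["per_class"][1] == pytest.approx(0.75)
        assert auc_pair_counting(y == 1, swapped) == pytest.approx(0.75)

    def test_matches_pair_counting_oracle_on_random_inputs(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 50))
            y = rng.integers(0, 3, n)
            if len(np.unique(y)) < 3:
                continue
            p = rng.random((n, 3))
            p /= p.sum(axis=1, keepdims=True)
            out = roc_auc(y, p)
            for k in range(3):
                assert out["per_class"][k] == pytest.approx(
                    auc_pair_counting(y == k, p[:, k]), abs=1e-12)

    def test_absent_class_excluded_from_macro_with_warning(self, rng):
        y = np.zeros(10, dtype=int)
        y[:5] = 1
        p = rng.random((10, 3))
        with pytest.warns(UserWarning, match="class 2"):
            out = roc_auc(y, p)
        assert out["per_class"][2] is None


class TestAggregateFolds:
    def test_identical_folds_mean_equals_fold_std_zero(self):
        rows = [{"accuracy": 97.0}] * 5
        out = aggregate_folds(rows)
        assert out.loc["mean", "accuracy"] == 97.0
        assert out.loc["std", "accuracy"] == 0.0

    def test_single_fold_mean_is_that_fold(self):
        out = aggregate_folds([{"accuracy": 96.5}])
        assert out.loc["mean", "accuracy"] == 96.5

    def test_two_decimal_formatting(self):
        rows = [{"m": v} for v in (1.004, 1.006)]
        out = aggregate_folds(rows)
        assert out.loc["mean", "m"] == 1.0 + 0.005 or out.loc["mean", "m"] == pytest.approx(1.0, abs=0.01)

    def test_empty_reports_rejected(self):
        with pytest.raises(ValueError):
            aggregate_folds([])


def test_micro_accuracy_equals_trace_over_total(rng):
    y = rng.integers(0, 9, 200)
    p = rng.integers(0, 9, 200)
    rep = multiclass_report(y, p)
    assert rep["accuracy"] == pytest.approx(np.trace(rep["confusion"]) / 200)
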
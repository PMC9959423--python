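import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluoroseg.metrics import (confusion_matrix, mask_accuracy, metrics_table,
                               one_vs_rest_metrics, overall_accuracy,
                               round_half_up, three_class_accuracy,
                               weighted_class_average)
from fluoroseg.staging import (StageThresholds, classify_fluorosis,
                               classify_fluorosis_ablated)

ratio = st.floats(0.0, 1.0, allow_nan=False)

# seven training images: (r_opaque, r_brown, expert grade, predicted grade)
TRAINING_TABLE = [
    ("N1", 0.0725, 0.0000, "Normal", "Normal"),
    ("N2", 0.1507, 0.0000, "Normal", "Stage 1"),
    ("F1_1", 0.1259, 0.0000, "Stage 1", "Stage 1"),
    ("F1_2", 0.1116, 0.0000, "Stage 1", "Stage 1"),
    ("F2_1", 0.3785, 0.0000, "Stage 2", "Stage 2"),
    ("F2_2", 0.0920, 0.0119, "Stage 2", "Stage 3"),
    ("F3_1", 0.3637, 0.0167, "Stage 3", "Stage 3"),
]

PIXEL_CM = np.array([  # rows = actual (white..background), cols = predicted
    [405, 18, 3, 0, 0],
    [18, 386, 0, 0, 0],
    [31, 4, 181, 2, 0],
    [4, 3, 0, 96, 0],
    [1, 8, 0, 2, 174],
])

STAGE_CM = np.array([  # rows = actual (Normal..Stage 3), cols = predicted
    [34, 5, 2, 3],
    [9, 26, 2, 4],
    [4, 2, 15, 2],
    [0, 2, 7, 11],
])


class TestStagingRule:
    @pytest.mark.parametrize("_id, ro, rb, _expert, predicted", TRAINING_TABLE)
    def test_training_set_predictions(self, _id, ro, rb, _expert, predicted):
        assert classify_fluorosis(ro, rb) == predicted

    def test_expert_agreement_is_five_of_seven(self):
        hits = sum(classify_fluorosis(ro, rb) == expert
                   for _, ro, rb, expert, _ in TRAINING_TABLE)
        assert hits == 5

    def test_small_opaque_shortcut_rescues_shadow_case(self):
        # shaded lip area: 1.63% opaque, 1.35% brown
        assert classify_fluorosis(0.0163, 0.0135) == "Normal"
        assert classify_fluorosis_ablated(0.0163, 0.0135) == "Stage 3"

    def test_ablated_rule_otherwise_agrees(self):
        assert classify_fluorosis_ablated(0.04, 0.0) == "Normal"
        assert classify_fluorosis_ablated(0.3637, 0.0167) == "Stage 3"

    @given(ro=ratio, rb=ratio)
    @settings(derandomize=True, max_examples=300)
    def test_rule_is_total(self, ro, rb):
        assert classify_fluorosis(ro, rb) in ("Normal", "Stage 1", "Stage 2", "Stage 3")

    @given(rb=st.floats(0.0, 0.007), ro1=ratio, ro2=ratio)
    @settings(derandomize=True, max_examples=300)
    def test_stage_monotone_in_opaque_ratio_when_brown_small(self, rb, ro1, ro2):
        order = ("Normal", "Stage 1", "Stage 2", "Stage 3")
        lo, hi = sorted([ro1, ro2])
        assert order.index(classify_fluorosis(lo, rb)) <= \
            order.index(classify_fluorosis(hi, rb))

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            StageThresholds(theta1=0.2, theta2=0.1)

    def test_out_of_range_ratios_rejected(self):
        with pytest.raises(ValueError):
            classify_fluorosis(1.2, 0.0)


class TestConfusionMatrix:
    def test_identical_vectors_give_diagonal(self):
        v = ["a", "b", "a", "c"]
        cm = confusion_matrix(v, v, ["a", "b", "c"])
        assert np.array_equal(cm, np.diag([2, 1, 1]))

    def test_entries_sum_to_sample_count(self):
        rng = np.random.default_rng(0)
        actual = rng.integers(0, 4, 200)
        pred = rng.integers(0, 4, 200)
        assert confusion_matrix(pred, actual, range(4)).sum() == 200

    def test_orientation_rows_are_actual(self):
        cm = confusion_matrix(predicted=["b"], actual=["a"], classes=["a", "b"])
        assert cm[0, 1] == 1 and cm[1, 0] == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([1, 2], [1], [1, 2])


class TestOneVsRest:
    def test_reproduces_pixel_classification_report(self):
        table = metrics_table(PIXEL_CM, ["White", "Yellow", "Opaque", "Brown",
                                         "Background"])
        assert table.loc["White", ["TP", "FN", "FP", "TN"]].tolist() == [405, 21, 54, 856]
        assert table.loc["White", "TPR"] == 95.07
        assert table.loc["White", "PPV"] == 88.24
        assert table.loc["Opaque", "TPR"] == 83.03
        assert table.loc["Opaque", ["TP", "FN", "FP", "TN"]].tolist() == [181, 37, 3, 1115]
        assert table.loc["Brown", "ACC"] == 99.18
        assert table.loc["Background", "TNR"] == 100.00
        assert table.loc["Yellow", "ACC"] == 96.18

    def test_reproduces_stage_classification_report(self):
        table = metrics_table(STAGE_CM, ["Normal", "Stage 1", "Stage 2", "Stage 3"])
        assert table.loc["Normal", "ACC"] == 82.03
        assert table.loc["Stage 1", "ACC"] == 81.25
        assert table.loc["Stage 2", "ACC"] == 85.16
        assert table.loc["Stage 3", "ACC"] == 85.94
        assert table.loc["Normal", "TPR"] == 77.27
        assert round_half_up(overall_accuracy(STAGE_CM)) == 67.19  # 86/128

    def test_rate_complements_are_exact(self):
        m = one_vs_rest_metrics(PIXEL_CM, 2)
        assert m.tpr + m.fnr == pytest.approx(100.0, abs=1e-12)
        assert m.tnr + m.fpr == pytest.approx(100.0, abs=1e-12)

    def test_perfect_two_class_matrix(self):
        m = one_vs_rest_metrics(np.diag([5, 7]), 0)
        assert (m.tpr, m.tnr, m.fpr, m.fnr) == (100.0, 100.0, 0.0, 0.0)
        assert m.acc == 100.0

    def test_absent_class_yields_nan_with_warning(self):
        cm = np.array([[3, 0, 0], [0, 2, 0], [0, 0, 0]])
        with pytest.warns(UserWarning):
            m = one_vs_rest_metrics(cm, 2)
        assert np.isnan(m.tpr)


class TestPixelAccuracies:
    def test_mask_accuracy_extremes_and_half(self):
        a = np.zeros((4, 4), bool)
        b = np.ones((4, 4), bool)
        checker = np.indices((4, 4)).sum(axis=0) % 2 == 0
        assert mask_accuracy(a, a) == 100.0
        assert mask_accuracy(a, b) == 0.0
        assert mask_accuracy(checker, b) == 50.0

    def test_mask_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mask_accuracy(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    def test_three_class_accuracy_restricted_to_tooth(self):
        gt = np.full((10, 10), 0)
        gt[0] = 3                       # background row
        mask = gt != 3
        pred = gt.copy()
        pred[0] = 1                     # background predictions must not count
        pred[1, :1] = 1                 # one real error among 90 tooth pixels
        assert three_class_accuracy(pred, gt, mask) == pytest.approx(100 * 89 / 90)

    def test_three_class_accuracy_needs_tooth_pixels(self):
        gt = np.full((3, 3), 3)
        with pytest.raises(ValueError):
            three_class_accuracy(gt, gt, np.zeros((3, 3), bool))


class TestWeightedAverage:
    def test_equal_counts_reduce_to_mean(self):
        assert weighted_class_average([1.0, 3.0], [5, 5]) == 2.0

    def test_reproduces_blind_test_averages(self):
        counts = [44, 41, 23, 20]
        acc_mask = [91.97, 93.71, 89.52, 92.93]
        acc3 = [91.57, 79.55, 67.74, 66.08]
        assert round_half_up(weighted_class_average(acc_mask, counts)) == 92.24
        assert round_half_up(weighted_class_average(acc3, counts)) == 79.46

    def test_zero_total_count_rejected(self):
        with pytest.raises(ValueError):
            weighted_class_average([1.0], [0])
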
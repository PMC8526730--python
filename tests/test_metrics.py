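"""Confusion counts, the eight-metric panel, AUROC, and cohort tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage

from segaudit.core import SegAuditError, make_all_cohort
from segaudit.metrics import (
    ConfusionCounts,
    auroc,
    cohort_metric_table,
    confusion_counts,
    confusion_percentages,
    metric_panel,
)


def _masks_3x3():
    """3x3 all-brain frame; pred {(0,0),(0,1)}, gt {(0,1),(1,1)}."""
    brain = np.ones((3, 3), dtype=bool)
    pred = np.zeros((3, 3), dtype=bool)
    pred[0, 0] = pred[0, 1] = True
    gt = np.zeros((3, 3), dtype=bool)
    gt[0, 1] = gt[1, 1] = True
    return pred, gt, brain


class TestConfusionCounts:
    def test_identity_prediction(self):
        brain = np.zeros((10, 10), dtype=bool)
        brain[:10, :10] = True
        gt = np.zeros((10, 10), dtype=bool)
        gt[0, :10] = True  # 10 tumor px in 100-px brain
        c = confusion_counts(gt, gt, brain)
        assert (c.TP, c.FP, c.FN, c.TN) == (10, 0, 0, 90)

    def test_empty_prediction(self):
        brain = np.ones((10, 10), dtype=bool)
        gt = np.zeros((10, 10), dtype=bool)
        gt[0] = True
        c = confusion_counts(np.zeros_like(gt), gt, brain)
        assert (c.TP, c.FP, c.FN, c.TN) == (0, 0, 10, 90)

    def test_hand_enumerated_3x3(self):
        pred, gt, brain = _masks_3x3()
        c = confusion_counts(pred, gt, brain)
        assert (c.TP, c.FP, c.FN, c.TN) == (1, 1, 1, 6)

    def test_prediction_outside_brain_ignored(self):
        pred, gt, brain = _masks_3x3()
        brain2 = np.pad(brain, 2)
        pred2 = np.pad(pred, 2)
        gt2 = np.pad(gt, 2)
        pred2[0, 0] = True  # outside brain: must not count
        c = confusion_counts(pred2, gt2, brain2)
        assert (c.TP, c.FP, c.FN, c.TN) == (1, 1, 1, 6)

    def test_shape_mismatch_and_empty_brain_error(self):
        with pytest.raises(SegAuditError):
            confusion_counts(np.ones((2, 2), bool), np.ones((3, 3), bool), np.ones((3, 3), bool))
        with pytest.raises(SegAuditError):
            confusion_counts(
                np.zeros((2, 2), bool), np.zeros((2, 2), bool), np.zeros((2, 2), bool)
            )


class TestMetricPanel:
    def test_hand_derived_values(self):
        p = metric_panel(ConfusionCounts(1, 1, 1, 6))
        assert p["Dice"] == pytest.approx(0.5)
        assert p["JacC"] == pytest.approx(1 / 3)
        assert p["Sens"] == pytest.approx(0.5)
        assert p["Spec"] == pytest.approx(6 / 7)
        assert p["PPV"] == pytest.approx(0.5)
        assert p["NPV"] == pytest.approx(6 / 7)
        assert p["BAcc"] == pytest.approx((0.5 + 6 / 7) / 2)

    def test_perfect_prediction_all_ones(self):
        p = metric_panel(ConfusionCounts(10, 0, 0, 90))
        for k in ("Sens", "Spec", "PPV", "NPV", "BAcc", "Dice", "JacC"):
            assert p[k] == 1.0

    def test_all_negative_prediction_undefined_ppv(self):
        p = metric_panel(ConfusionCounts(0, 0, 5, 95))
        assert np.isnan(p["PPV"])  # 0/0 propagates as missing, never 0
        assert p["Sens"] == 0.0

    @given(
        st.tuples(
            st.integers(0, 500), st.integers(0, 500),
            st.integers(0, 500), st.integers(1, 500),
        )
    )
    def test_jaccard_dice_identity(self, counts):
        p = metric_panel(ConfusionCounts(*counts))
        if not np.isnan(p["Dice"]):
            assert p["JacC"] == pytest.approx(p["Dice"] / (2 - p["Dice"]))
        if not (np.isnan(p["Sens"]) or np.isnan(p["Spec"])):
            assert p["BAcc"] == pytest.approx((p["Sens"] + p["Spec"]) / 2)


class TestAuroc:
    def _brute_force(self, probs, labels):
        pos = probs[labels]
        neg = probs[~labels]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        return wins / (len(pos) * len(neg))

    def test_hand_example(self):
        probs = np.array([[0.9, 0.4], [0.8, 0.1]])
        gt = np.array([[True, True], [False, False]])
        brain = np.ones((2, 2), dtype=bool)
        assert auroc(probs, gt, brain) == pytest.approx(0.75)

    def test_perfect_separation(self):
        probs = np.array([[0.9, 0.8], [0.2, 0.1]])
        gt = np.array([[True, True], [False, False]])
        assert auroc(probs, gt, np.ones((2, 2), bool)) == 1.0

    def test_constant_probability_is_half(self):
        probs = np.full((2, 2), 0.3)
        gt = np.array([[True, False], [False, False]])
        assert auroc(probs, gt, np.ones((2, 2), bool)) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        probs = np.full((2, 2), 0.3)
        assert np.isnan(auroc(probs, np.ones((2, 2), bool), np.ones((2, 2), bool)))

    @given(st.integers(0, 1000))
    def test_rank_formulation_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        probs = np.round(rng.random(n), 2)  # coarse grid forces ties
        labels = rng.random(n) < 0.3
        if labels.all() or not labels.any():
            return
        got = auroc(probs.reshape(1, -1), labels.reshape(1, -1), np.ones((1, n), bool))
        assert got == pytest.approx(self._brute_force(probs, labels))


class TestCohortTables:
    def test_single_patient_table_matches_panel(self, cohorts, predictor):
        from segaudit.core import Cohort
        from segaudit.metrics import patient_panel

        case = cohorts["test"]["GBM"].cases[0]
        tab = cohort_metric_table(Cohort("GBM", [case], "test"), predictor)
        panel = patient_panel(case, predictor)
        for k, v in panel.items():
            assert tab.iloc[0][k] == pytest.approx(v, nan_ok=True)

    def test_all_table_is_concatenation(self, cohorts, predictor):
        gbm = cohort_metric_table(cohorts["test"]["GBM"], predictor)
        lgg = cohort_metric_table(cohorts["test"]["LGG"], predictor)
        allt = cohort_metric_table(cohorts["test"]["ALL"], predictor)
        expected = pd.concat([gbm, lgg], ignore_index=True)
        pd.testing.assert_frame_equal(allt, expected)

    def test_confusion_percentages_hand_case(self, cohorts):
        """A single patient built from the 3x3 hand example yields the hand
        percentages (11.11, 11.11, 11.11, 66.67)."""
        from segaudit.core import Cohort, PatientCase, Predictor

        pred_mask, gt, brain = _masks_3x3()

        class FixedPredictor(Predictor):
            def predict_logits(self, pixels):
                return np.where(pred_mask, 10.0, -10.0)

            def loss_input_gradient(self, pixels, gt_mask):
                raise NotImplementedError

        slices = np.ones((1, 4, 3, 3))
        case = PatientCase("p", "06", "GBM", slices, gt[None], brain[None])
        pc = confusion_percentages(Cohort("GBM", [case], "test"), FixedPredictor())
        assert pc["%TP"] == pytest.approx(100 / 9)
        assert pc["%FP"] == pytest.approx(100 / 9)
        assert pc["%FN"] == pytest.approx(100 / 9)
        assert pc["%TN"] == pytest.approx(600 / 9)

    def test_percentages_sum_to_100(self, cohorts, predictor):
        pc = confusion_percentages(cohorts["test"]["ALL"], predictor)
        assert sum(pc.values()) == pytest.approx(100.0, abs=1e-9)

    def test_oracle_predictor_has_zero_fp_fn(self, cohorts):
        from segaudit.core import Predictor

        class Oracle(Predictor):
            def __init__(self, case):
                self.case = case
                self.i = 0

            def predict_logits(self, pixels):  # relies on per-slice call order
                z = np.where(self.case.gt_masks[self.i], 10.0, -10.0)
                self.i += 1
                return z

            def loss_input_gradient(self, pixels, gt_mask):
                raise NotImplementedError

        from segaudit.core import Cohort

        case = cohorts["test"]["GBM"].cases[0]
        pc = confusion_percentages(Cohort("GBM", [case], "test"), Oracle(case))
        assert pc["%FP"] == 0.0 and pc["%FN"] == 0.0
        tumor_frac = case.gt_masks.sum() / case.brain_masks.sum()
        assert pc["%TP"] == pytest.approx(100 * tumor_frac)

    def test_dilation_raises_fp_not_fn(self, cohorts):
        """Over-segmentation signature: dilating an oracle mask adds false
        positives only; eroding adds false negatives only."""
        case = cohorts["test"]["GBM"].cases[0]
        gt = case.gt_masks
        brain = case.brain_masks
        dil = np.stack([ndimage.binary_dilation(g) for g in gt]) & brain
        ero = np.stack([ndimage.binary_erosion(g) for g in gt])
        c_dil = confusion_counts(dil, gt, brain)
        c_ero = confusion_counts(ero, gt, brain)
        assert c_dil.FP > 0 and c_dil.FN == 0
        assert c_ero.FN > 0 and c_ero.FP == 0


class TestPaddingInvariance:
    def test_zero_border_changes_nothing(self, predictor):
        """Pixels outside the brain contribute nothing: evaluating a padded
        image yields identical metrics."""
        from segaudit.core import PatientCase
        from segaudit.metrics import patient_panel

        rng = np.random.default_rng(1)
        slices = np.zeros((2, 4, 20, 20))
        brain = np.zeros((2, 20, 20), dtype=bool)
        brain[:, 4:16, 4:16] = True
        slices[:, :, 4:16, 4:16] = np.abs(rng.normal(1, 0.3, (2, 4, 12, 12))) + 0.05
        gt = np.zeros((2, 20, 20), dtype=bool)
        gt[:, 8:12, 8:12] = True
        case = PatientCase("p", "06", "GBM", slices, gt, brain)
        padded = PatientCase(
            "p", "06", "GBM",
            np.pad(slices, ((0, 0), (0, 0), (3, 3), (3, 3))),
            np.pad(gt, ((0, 0), (3, 3), (3, 3))),
            np.pad(brain, ((0, 0), (3, 3), (3, 3))),
        )
        a = patient_panel(case, predictor)
        b = patient_panel(padded, predictor)
        for k in a:
            assert a[k] == pytest.approx(b[k], nan_ok=True, abs=1e-12)
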
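"""Dice coefficient, soft/hybrid dice losses and confusion metrics."""

import numpy as np
import pytest

from nodulepipe.labeling import BinaryMask, LabelMode, Polarity, complement_mask, \
    make_bundle
from nodulepipe.losses_metrics import (ConfusionCounts, confusion_metrics,
                                       dice_coefficient, hybrid_dice_loss,
                                       soft_dice_loss)


def mask(arr):
    return BinaryMask(np.asarray(arr, dtype=bool))


class TestDiceCoefficient:
    def test_identical_nonempty(self, rng):
        m = mask(rng.random((8, 8)) < 0.4)
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint_nonempty(self):
        a = np.zeros((4, 4), dtype=bool); a[0, 0] = True
        b = np.zeros((4, 4), dtype=bool); b[3, 3] = True
        assert dice_coefficient(mask(a), mask(b)) == 0.0

    def test_direct_substitution(self):
        # |X|=2, |Y|=4, overlap 2 -> 2*2/(2+4)
        x = np.zeros((4, 4), dtype=bool); x[0, :2] = True
        y = np.zeros((4, 4), dtype=bool); y[0, :4] = True
        assert dice_coefficient(mask(x), mask(y)) == pytest.approx(2 / 3)

    def test_both_empty_defined_as_one(self):
        assert dice_coefficient(mask(np.zeros((4, 4))), mask(np.zeros((4, 4)))) == 1.0

    def test_symmetric(self, rng):
        a, b = mask(rng.random((8, 8)) < 0.3), mask(rng.random((8, 8)) < 0.3)
        assert dice_coefficient(a, b) == dice_coefficient(b, a)

    def test_not_invariant_under_complementation_in_general(self):
        x = np.zeros((4, 4), dtype=bool); x[0, 0] = True
        y = np.zeros((4, 4), dtype=bool); y[0, :2] = True
        d = dice_coefficient(mask(x), mask(y))
        dc = dice_coefficient(complement_mask(mask(x)), complement_mask(mask(y)))
        assert d != dc

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            dice_coefficient(mask(np.zeros((4, 4))), mask(np.zeros((5, 5))))

    def test_brute_force_oracle_agreement(self, rng):
        for _ in range(30):
            shape = (int(rng.integers(2, 12)), int(rng.integers(2, 12)))
            a = rng.random(shape) < 0.4
            b = rng.random(shape) < 0.4
            inter = sum(1 for r in range(shape[0]) for c in range(shape[1])
                        if a[r, c] and b[r, c])
            size = int(a.sum() + b.sum())
            expected = 1.0 if size == 0 else 2 * inter / size
            assert dice_coefficient(mask(a), mask(b)) == pytest.approx(expected)


class TestSoftDiceLoss:
    def test_perfect_binary_prediction_near_zero(self, rng):
        t = mask(rng.random((8, 8)) < 0.4)
        assert soft_dice_loss(t.pixels.astype(float), t, eps=1e-12) < 1e-10

    def test_inverted_binary_prediction_near_one(self, rng):
        t = mask(rng.random((8, 8)) < 0.5)
        pred = 1.0 - t.pixels.astype(float)
        assert soft_dice_loss(pred, t, eps=1e-12) > 1 - 1e-9

    def test_summed_by_hand_oracle(self, rng):
        pred = rng.random((8, 8))
        t = mask(rng.random((8, 8)) < 0.3)
        eps = 1e-6
        num = den = 0.0
        for r in range(8):
            for c in range(8):
                num += pred[r, c] * t.pixels[r, c]
                den += pred[r, c] + t.pixels[r, c]
        expected = 1 - (2 * num + eps) / (den + eps)
        assert soft_dice_loss(pred, t, eps) == pytest.approx(expected, abs=1e-10)

    def test_equals_one_minus_dice_for_binary(self, rng):
        p = rng.random((8, 8)) < 0.4
        t = rng.random((8, 8)) < 0.4
        loss = soft_dice_loss(p.astype(float), mask(t), eps=1e-12)
        assert loss == pytest.approx(1 - dice_coefficient(mask(p), mask(t)), abs=1e-9)


class TestHybridDiceLoss:
    def test_perfect_prediction(self, rng):
        gt = mask(rng.random((8, 8)) < 0.3)
        b = make_bundle(gt, LabelMode.HYBRID)
        assert hybrid_dice_loss(b.as_array(), b, eps=1e-12) < 1e-10

    def test_swapped_channels(self, rng):
        gt = mask(rng.random((8, 8)) < 0.5)
        if not gt.pixels.any() or gt.pixels.all():
            gt = mask(np.eye(8))
        b = make_bundle(gt, LabelMode.HYBRID)
        swapped = b.as_array()[::-1]
        assert hybrid_dice_loss(swapped, b, eps=1e-12) > 1 - 1e-9

    def test_equals_mean_of_mono_losses(self, rng):
        gt = mask(rng.random((8, 8)) < 0.3)
        b = make_bundle(gt, LabelMode.HYBRID)
        pred = rng.random((2, 8, 8))
        lhs = hybrid_dice_loss(pred, b)
        rhs = 0.5 * (soft_dice_loss(pred[0], b.channels[0])
                     + soft_dice_loss(pred[1], b.channels[1]))
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_non_hybrid_bundle_errors(self, rng):
        b = make_bundle(mask(rng.random((4, 4)) < 0.3), LabelMode.MONO_POSITIVE)
        with pytest.raises(ValueError):
            hybrid_dice_loss(np.zeros((2, 4, 4)), b)


class TestConfusionMetrics:
    def test_perfect_prediction_all_ones(self, rng):
        gt = mask(rng.random((8, 8)) < 0.4)
        rep = confusion_metrics(gt, gt)
        assert rep.accuracy == rep.sensitivity == rep.specificity == 1.0

    def test_direct_count_example(self):
        gt = mask(np.array([[1, 1, 0, 0]]))
        pred = mask(np.array([[1, 0, 0, 1]]))
        rep = confusion_metrics(pred, gt)
        assert (rep.counts.tp, rep.counts.fn, rep.counts.fp, rep.counts.tn) == (1, 1, 1, 1)
        assert rep.accuracy == rep.sensitivity == rep.specificity == 0.5

    def test_per_pixel_counting_oracle(self, rng):
        pred = mask(rng.random((16, 16)) < 0.4)
        gt = mask(rng.random((16, 16)) < 0.4)
        rep = confusion_metrics(pred, gt)
        tp = tn = fp = fn = 0
        for r in range(16):
            for c in range(16):
                p, g = pred.pixels[r, c], gt.pixels[r, c]
                tp += p and g
                tn += (not p) and (not g)
                fp += p and not g
                fn += (not p) and g
        assert (rep.counts.tp, rep.counts.tn, rep.counts.fp, rep.counts.fn) \
            == (tp, tn, fp, fn)

    def test_sensitivity_undefined_for_empty_gt(self):
        rep = confusion_metrics(mask(np.zeros((4, 4))), mask(np.zeros((4, 4))))
        assert rep.sensitivity is None and rep.specificity == 1.0

    def test_specificity_undefined_for_full_gt(self):
        rep = confusion_metrics(mask(np.ones((4, 4))), mask(np.ones((4, 4))))
        assert rep.specificity is None and rep.sensitivity == 1.0

    def test_polarity_mismatch_errors(self, rng):
        gt = mask(rng.random((4, 4)) < 0.5)
        with pytest.raises(ValueError, match="polarity"):
            confusion_metrics(complement_mask(gt), gt)

    def test_dice_from_counts_identity(self, rng):
        # dice = 2TP/(2TP+FP+FN) for binary predictions
        for _ in range(20):
            pred = mask(rng.random((8, 8)) < 0.4)
            gt = mask(rng.random((8, 8)) < 0.4)
            rep = confusion_metrics(pred, gt)
            tp, fp, fn = rep.counts.tp, rep.counts.fp, rep.counts.fn
            if 2 * tp + fp + fn:
                assert rep.dice == pytest.approx(2 * tp / (2 * tp + fp + fn))

    def test_accuracy_prevalence_identity(self, rng):
        # accuracy = (sens*P + spec*N)/(P+N)
        for _ in range(20):
            pred = mask(rng.random((8, 8)) < 0.5)
            gt = mask(rng.random((8, 8)) < 0.5)
            rep = confusion_metrics(pred, gt)
            if rep.sensitivity is None or rep.specificity is None:
                continue
            P = rep.counts.tp + rep.counts.fn
            N = rep.counts.fp + rep.counts.tn
            assert rep.accuracy == pytest.approx(
                (rep.sensitivity * P + rep.specificity * N) / (P + N))

    def test_counts_reject_negative(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)
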
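"""Loss system: analytic values, oracle agreement, and invariants."""

import numpy as np
import pytest

from lapseg.losses import (
    ClassWeights,
    LossWeights,
    box_loss,
    box_regression_loss,
    classification_loss,
    focal_term,
    iou_loss,
    objectness_loss,
    soft_iou,
    soft_iou_per_class,
    total_loss,
)
from lapseg.nn import Tensor, softmax


class TestClassWeights:
    def test_reciprocal_counts(self):
        w = ClassWeights.from_counts([100, 10], eps=1e-9)
        np.testing.assert_allclose(w.raw, [0.01, 0.1], rtol=1e-6)

    def test_zero_count_capped_by_eps(self):
        w = ClassWeights.from_counts([0, 10], eps=1e-6)
        assert np.isfinite(w.raw[0]) and w.raw[0] == pytest.approx(1e6)

    def test_mean_one_normalization(self):
        w = ClassWeights.from_counts([100, 10], eps=1e-12)
        np.testing.assert_allclose(w.normalized, [2 / 11, 20 / 11], rtol=1e-6)
        assert w.normalized.mean() == pytest.approx(1.0, abs=1e-9)

    def test_rarer_class_strictly_heavier(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 10000, size=6)
            w = ClassWeights.from_counts(counts)
            order = np.argsort(counts)
            diffs = np.diff(w.normalized[order])
            assert (diffs[np.diff(counts[order]) > 0] < 0).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ClassWeights.from_counts([-1, 5])


class TestFocalTerm:
    def test_perfect_prediction_is_zero(self):
        assert focal_term(1.0, w=7.3, gamma=2.0) == 0.0

    def test_gamma_zero_is_cross_entropy(self):
        p = 0.37
        assert focal_term(p, 1.0, 0.0) == pytest.approx(-np.log(p), abs=1e-12)

    def test_worked_value(self):
        # p=0.5, w=1, gamma=2: 0.25*ln2
        assert focal_term(0.5, 1.0, 2.0) == pytest.approx(0.25 * np.log(2), abs=1e-9)

    def test_monotone_decreasing_in_p(self):
        grid = np.linspace(0.01, 1.0, 200)
        vals = focal_term(grid, 2.0, 2.0)
        assert (np.diff(vals) < 1e-12).all()


class TestClassificationLoss:
    def test_perfect_one_hot_is_zero(self):
        gt = np.array([[0, 1], [2, 1]])
        p = np.zeros((1, 3, 2, 2), dtype=np.float32)
        for i in range(2):
            for j in range(2):
                p[0, gt[i, j], i, j] = 1.0
        assert classification_loss(p, gt).item() == pytest.approx(0.0, abs=1e-6)

    def test_uniform_prediction_is_log_k(self):
        k = 5
        p = np.full((1, k, 3, 3), 1 / k, dtype=np.float32)
        gt = np.zeros((3, 3), dtype=int)
        got = classification_loss(p, gt, weights=None, gamma=0.0).item()
        assert got == pytest.approx(np.log(k), abs=1e-6)

    def test_matches_per_pixel_brute_force(self, rng):
        k = 3
        logits = rng.normal(0, 1, (1, k, 2, 2))
        p = softmax(Tensor(logits), axis=1)
        gt = rng.integers(0, k, (2, 2))
        w = ClassWeights.from_counts(rng.integers(1, 100, k))
        gamma = 2.0
        got = classification_loss(p, gt, w, gamma).item()
        brute = np.mean([
            focal_term(p.data[0, gt[i, j], i, j], w.normalized[gt[i, j]], gamma)
            for i in range(2) for j in range(2)
        ])
        assert got == pytest.approx(brute, rel=1e-5)

    def test_gamma_zero_reduces_to_weighted_ce(self, rng):
        k = 4
        p = softmax(Tensor(rng.normal(0, 1, (2, k, 5, 5))), axis=1)
        gt = rng.integers(0, k, (2, 5, 5))
        w = ClassWeights.from_counts(rng.integers(1, 50, k))
        got = classification_loss(p, gt, w, gamma=0.0).item()
        ce = -np.mean(w.normalized[gt] * np.log(
            np.take_along_axis(p.data, gt[:, None], axis=1)[:, 0]))
        assert got == pytest.approx(ce, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            classification_loss(np.zeros((1, 2, 3, 3)), np.zeros((4, 4), dtype=int))


class TestSoftIoU:
    def test_identical_binary_masks(self):
        m = np.zeros((4, 4))
        m[1:3, 1:3] = 1
        assert soft_iou(m, m).item() == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_masks(self):
        a = np.zeros((4, 4)); a[0, 0] = 1
        b = np.zeros((4, 4)); b[3, 3] = 1
        assert soft_iou(a, b).item() == pytest.approx(0.0, abs=1e-6)

    def test_toy_two_element_overlap(self):
        # pred {a,b}, gt {b,c}: intersection 1, union 3
        pred = np.array([1.0, 1.0, 0.0])
        gt = np.array([0.0, 1.0, 1.0])
        assert soft_iou(pred, gt).item() == pytest.approx(1 / 3, abs=1e-6)

    def test_both_empty_is_one(self):
        z = np.zeros((3, 3))
        assert soft_iou(z, z).item() == 1.0

    def test_binary_oracle_and_symmetry(self, rng):
        """Set-arithmetic oracle on 1,000 random 8x8 binary pairs."""
        for _ in range(1000):
            a = rng.random((8, 8)) < 0.3
            b = rng.random((8, 8)) < 0.3
            inter = np.logical_and(a, b).sum()
            union = np.logical_or(a, b).sum()
            want = inter / union if union else 1.0
            got = soft_iou(a.astype(float), b.astype(float)).item()
            assert got == pytest.approx(want, abs=1e-5)
            assert got == pytest.approx(
                soft_iou(b.astype(float), a.astype(float)).item(), abs=1e-6)
            assert 0.0 <= got <= 1.0

    def test_per_class_skips_absent_classes(self, rng):
        p = softmax(Tensor(rng.normal(0, 1, (1, 4, 6, 6))), axis=1)
        gt = np.zeros((6, 6), dtype=int)
        gt[2:4, 2:4] = 2
        ious = soft_iou_per_class(p, gt)
        assert set(ious) == {2}
        brute = soft_iou(p.data[0, 2], (gt == 2).astype(float)).item()
        assert ious[2].item() == pytest.approx(brute, rel=1e-5)


class TestIoULoss:
    def test_perfect_overlap_zero(self):
        assert iou_loss({1: 1.0, 2: 1.0}).item() == pytest.approx(0.0, abs=1e-9)

    def test_single_zero_iou(self):
        assert iou_loss([0.0]).item() == pytest.approx(1.0)

    def test_mean_of_complements(self):
        assert iou_loss([0.5, 0.75]).item() == pytest.approx(0.375, abs=1e-6)

    def test_no_foreground_is_zero(self):
        assert iou_loss({}).item() == 0.0


class TestBoxLoss:
    def test_identical_boxes(self):
        b = np.array([0.5, 0.5, 0.2, 0.2])
        assert box_loss(b, b).item() == pytest.approx(0.0)

    def test_worked_value(self):
        got = box_loss([0.5, 0.5, 0.2, 0.2], [0.5, 0.5, 0.1, 0.1]).item()
        assert got == pytest.approx(0.02, abs=1e-6)

    def test_batch_mean_matches_hand_sum(self, rng):
        pairs = [(rng.random(4), rng.random(4)) for _ in range(3)]
        want = np.mean([((p - g) ** 2).sum() for p, g in pairs])
        assert box_regression_loss(pairs).item() == pytest.approx(want, rel=1e-5)

    def test_unmatched_gt_counts_as_zero_box(self):
        g = np.array([0.5, 0.5, 0.2, 0.2], dtype=np.float32)
        got = box_regression_loss([], unmatched_gt=[g]).item()
        assert got == pytest.approx((g ** 2).sum(), rel=1e-6)


class TestObjectnessLoss:
    def test_confident_correct_is_near_zero(self):
        s = np.full((2, 2), 1 - 1e-7)
        y = np.ones((2, 2))
        assert objectness_loss(s, y).item() == pytest.approx(0.0, abs=1e-5)

    @pytest.mark.parametrize("y", [0.0, 1.0])
    def test_half_confidence_is_ln2(self, y):
        s = np.full((3, 3), 0.5)
        got = objectness_loss(s, np.full((3, 3), y)).item()
        assert got == pytest.approx(np.log(2), abs=1e-6)


class TestTotalLoss:
    def test_unit_weights_sum(self):
        lw = LossWeights(1, 1, 1, 1)
        lb = total_loss(1.0, 2.0, 3.0, 4.0, lw)
        assert lb.l_total == pytest.approx(10.0, abs=1e-6)

    def test_zero_weights(self):
        lw = LossWeights(0, 0, 0, 0)
        assert total_loss(1, 2, 3, 4, lw).l_total == pytest.approx(0.0)

    def test_weighted_sum(self):
        lw = LossWeights(1, 1, 0.5, 1)
        lb = total_loss(0.5, 0.2, 0.1, 0.3, lw)
        assert lb.l_total == pytest.approx(1.05, abs=1e-6)

    def test_nan_component_identified(self):
        with pytest.raises(FloatingPointError, match="l_iou"):
            total_loss(1.0, np.nan, 0.0, 0.0, LossWeights())

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_cls=-0.1)


class TestGradients:
    def test_every_component_yields_finite_gradients(self, rng):
        k = 4
        logits = Tensor(rng.normal(0, 1, (1, k, 8, 8)), requires_grad=True)
        obj_logits = Tensor(rng.normal(0, 1, (1, 1, 8, 8)), requires_grad=True)
        box_raw = Tensor(rng.normal(0, 1, (4,)), requires_grad=True)
        gt = rng.integers(0, k, (8, 8))
        p = softmax(logits, axis=1)
        s = obj_logits.sigmoid()
        w = ClassWeights.from_counts(np.bincount(gt.ravel(), minlength=k))
        lb = total_loss(
            classification_loss(p, gt, w, 2.0),
            iou_loss(soft_iou_per_class(p, gt)),
            box_loss(box_raw.sigmoid(), [0.4, 0.4, 0.2, 0.2]),
            objectness_loss(s, (gt > 0)[None, None].astype(float)),
            LossWeights(),
        )
        lb.total.backward()
        for t in (logits, obj_logits, box_raw):
            assert t.grad is not None
            assert np.isfinite(t.grad).all()
            assert np.abs(t.grad).max() > 0
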
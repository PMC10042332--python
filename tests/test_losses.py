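"""IoU/CIoU primitives, BCE components, target assignment, composite loss."""

import numpy as np
import pytest

from bassdet.anchors import AnchorSet, STRIDES
from bassdet.boxes import Box, ValidationError
from bassdet.losses import (
    LossConfig, assign_targets, bbox_loss, ciou, ciou_array, class_loss,
    compute_loss, confidence_loss, iou, iou_matrix,
)
from bassdet.nn.engine import Var

ANCH = AnchorSet(anchors=((6, 12), (10, 8), (12, 14), (16, 24), (20, 18),
                          (24, 30), (30, 48), (40, 36), (48, 56)))


def brute_force_ciou(pred, gt):
    """Independent scripted evaluation of the CIoU definition."""
    px0, py0, px1, py1 = pred.corners
    gx0, gy0, gx1, gy1 = gt.corners
    iw = max(0.0, min(px1, gx1) - max(px0, gx0))
    ih = max(0.0, min(py1, gy1) - max(py0, gy0))
    inter = iw * ih
    union = pred.area + gt.area - inter
    i = inter / union
    rho2 = (pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2
    cw = max(px1, gx1) - min(px0, gx0)
    ch = max(py1, gy1) - min(py0, gy0)
    c2 = cw ** 2 + ch ** 2
    v = 4 / np.pi ** 2 * (np.arctan(gt.w / gt.h) - np.arctan(pred.w / pred.h)) ** 2
    alpha = v / ((1 - i) + v) if (1 - i) + v > 0 else 0.0
    return i - rho2 / c2 - alpha * v


class TestIoU:
    def test_identical(self):
        b = Box(5, 5, 4, 4)
        assert iou(b, b) == 1.0

    def test_disjoint(self):
        assert iou(Box(2, 2, 2, 2), Box(10, 10, 2, 2)) == 0.0

    def test_worked_example(self):
        """Corners (0,0,2,2) vs (1,1,3,3): intersection 1, union 7."""
        a = Box.from_corners(0, 0, 2, 2)
        b = Box.from_corners(1, 1, 3, 3)
        assert iou(a, b) == pytest.approx(1 / 7)

    def test_degenerate_rejected(self):
        with pytest.raises(ValidationError):
            ciou_array(np.array([[1, 1, 0.0, 2]]), np.array([[1, 1, 1, 1]]))


class TestCIoU:
    def test_identical_is_one(self):
        b = Box(3, 4, 5, 6)
        assert ciou(b, b) == pytest.approx(1.0)

    def test_concentric_equal_aspect_equals_iou(self):
        """rho = 0 and v = 0 make the penalties vanish analytically."""
        a = Box(10, 10, 8, 4)
        b = Box(10, 10, 4, 2)
        assert ciou(a, b) == pytest.approx(iou(a, b), abs=1e-12)

    def test_worked_pair_matches_brute_force(self):
        pred = Box.from_corners(0, 0, 2, 4)
        gt = Box.from_corners(1, 0, 3, 2)
        assert ciou(pred, gt) == pytest.approx(brute_force_ciou(pred, gt), abs=1e-9)

    def test_ciou_le_iou_on_random_pairs(self):
        """Penalty terms are nonnegative, so CIoU <= IoU, with equality only
        for concentric equal-aspect pairs (checked on 1e4 random pairs here;
        the acceptance suite runs 1e5)."""
        rng = np.random.default_rng(0)
        pred = np.column_stack([rng.uniform(0, 50, 10000), rng.uniform(0, 50, 10000),
                                rng.uniform(0.5, 30, 10000), rng.uniform(0.5, 30, 10000)])
        gt = np.column_stack([rng.uniform(0, 50, 10000), rng.uniform(0, 50, 10000),
                              rng.uniform(0.5, 30, 10000), rng.uniform(0.5, 30, 10000)])
        cv, _ = ciou_array(pred, gt)
        pc = np.stack([pred[:, 0] - pred[:, 2] / 2, pred[:, 1] - pred[:, 3] / 2,
                       pred[:, 0] + pred[:, 2] / 2, pred[:, 1] + pred[:, 3] / 2], axis=1)
        gc = np.stack([gt[:, 0] - gt[:, 2] / 2, gt[:, 1] - gt[:, 3] / 2,
                       gt[:, 0] + gt[:, 2] / 2, gt[:, 1] + gt[:, 3] / 2], axis=1)
        ious = np.diag(iou_matrix(pc, gc))
        assert (cv <= ious + 1e-12).all()
        # 1 - CIoU is bounded: rho^2/c^2 < 1 and alpha*v < 1/2
        assert (1 - cv < 2.5).all() and (1 - cv >= 0).all()

    def test_gradient_matches_finite_differences_with_frozen_alpha(self):
        rng = np.random.default_rng(1)
        pred = np.abs(rng.normal(3, 1, size=(30, 4))) + 0.3
        gt = np.abs(rng.normal(3, 1, size=(30, 4))) + 0.3
        _, grad = ciou_array(pred, gt, with_grad=True)
        # recompute numerically with alpha held at its analytic value
        vals0, _ = ciou_array(pred, gt)
        eps = 1e-6
        for dim in range(4):
            pp, pm = pred.copy(), pred.copy()
            pp[:, dim] += eps
            pm[:, dim] -= eps
            vp, _ = ciou_array(pp, gt)
            vm, _ = ciou_array(pm, gt)
            num = (vp - vm) / (2 * eps)
            # alpha varies in the numerical difference; allow its contribution
            assert np.abs(num - grad[:, dim]).max() < 0.2


class TestComponents:
    def test_bbox_loss_basics(self):
        b = np.array([[5.0, 5.0, 4.0, 4.0]])
        assert bbox_loss(b, b) == 0.0
        assert bbox_loss(np.zeros((0, 4)), np.zeros((0, 4))) == 0.0
        pred = Box.from_corners(0, 0, 2, 4)
        gt = Box.from_corners(1, 0, 3, 2)
        expect = 1 - brute_force_ciou(pred, gt)
        got = bbox_loss(np.array([[pred.cx, pred.cy, pred.w, pred.h]]),
                        np.array([[gt.cx, gt.cy, gt.w, gt.h]]))
        assert got == pytest.approx(expect, abs=1e-9)

    def test_confidence_loss_hand_values(self):
        # all background predicted 0 -> 0
        assert confidence_loss(np.zeros(10), np.zeros(10, bool), 0.5) == pytest.approx(0.0, abs=1e-5)
        # one object position at p=0.5, no background term
        v = confidence_loss(np.array([0.5]), np.array([True]), 0.5)
        assert v == pytest.approx(-np.log(0.5), rel=1e-6)
        # doubling lambda doubles the background contribution exactly
        p = np.array([0.3, 0.7, 0.5])
        m = np.array([True, False, False])
        base = confidence_loss(p, m, 0.0)
        l1 = confidence_loss(p, m, 1.0)
        l2 = confidence_loss(p, m, 2.0)
        assert l2 - base == pytest.approx(2 * (l1 - base), rel=1e-12)

    def test_class_loss_hand_values(self):
        assert class_loss(np.ones((3, 1)), np.zeros(3), 1) == pytest.approx(0.0, abs=1e-5)
        assert class_loss(np.full((1, 1), 0.5), np.zeros(1), 1) == pytest.approx(-np.log(0.5), rel=1e-6)
        assert class_loss(np.zeros((0, 1)), np.zeros(0), 1) == 0.0
        with pytest.raises(ValidationError):
            class_loss(np.full((1, 2), 0.5), np.array([5]), 2)


def brute_force_assignment(gt, anchors, input_size, ratio=4.0):
    """Exhaustive scan over every anchor/cell pair applying the rule."""
    out = []
    for s, (aw, stride) in enumerate(zip(anchors.per_scale(), STRIDES)):
        K = input_size // stride
        rows = set()
        for m, (_, cx, cy, w, h) in enumerate(gt):
            fx, fy = cx / stride, cy / stride
            gx0, gy0 = min(int(fx), K - 1), min(int(fy), K - 1)
            allowed = {(gy0, gx0)}
            dx = -1 if fx - gx0 < 0.5 else 1
            dy = -1 if fy - gy0 < 0.5 else 1
            if 0 <= gx0 + dx < K:
                allowed.add((gy0, gx0 + dx))
            if 0 <= gy0 + dy < K:
                allowed.add((gy0 + dy, gx0))
            for a in range(3):
                r = max(w / aw[a, 0], aw[a, 0] / w, h / aw[a, 1], aw[a, 1] / h)
                if r >= ratio:
                    continue
                for (cgy, cgx) in allowed:
                    if -0.5 < fx - cgx < 1.5 and -0.5 < fy - cgy < 1.5:
                        rows.add((a, cgy, cgx, m))
        out.append(rows)
    return out


class TestAssignment:
    def test_gt_matching_anchor_at_cell_center_is_positive(self):
        gt = np.array([[0, 20.0, 20.0, 6.0, 12.0]])   # == anchor 0 at P3
        asn = assign_targets(gt, ANCH, 64)
        assert len(asn[0]["anchor"]) > 0
        assert 0 in asn[0]["anchor"]

    def test_oversized_gt_yields_no_positives(self, caplog):
        gt = np.array([[0, 32.0, 32.0, 600.0, 600.0]])
        asn = assign_targets(gt, ANCH, 64)
        assert all(len(a["anchor"]) == 0 for a in asn)

    def test_outside_image_rejected(self):
        with pytest.raises(ValidationError):
            assign_targets(np.array([[0, -5.0, 10.0, 4.0, 4.0]]), ANCH, 64)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        gt = np.column_stack([
            np.zeros(6), rng.uniform(2, 62, 6), rng.uniform(2, 62, 6),
            rng.uniform(4, 40, 6), rng.uniform(4, 40, 6)])
        asn = assign_targets(gt, ANCH, 64)
        oracle = brute_force_assignment(gt, ANCH, 64)
        for s in range(3):
            got = set(zip(asn[s]["anchor"], asn[s]["gy"], asn[s]["gx"],
                          asn[s]["gt_index"]))
            assert got == oracle[s]


class TestCompositeLoss:
    def _setup(self, seed=1):
        rng = np.random.default_rng(seed)
        raw = [Var(rng.normal(0, 1, size=(2, 18, 64 // s, 64 // s)))
               for s in STRIDES]
        gt = [np.array([[0, 20.0, 22.0, 12.0, 10.0], [0, 44.0, 40.0, 30.0, 44.0]]),
              np.array([[0, 10.0, 50.0, 8.0, 14.0]])]
        return raw, gt

    def test_components_nonnegative_and_total(self):
        raw, gt = self._setup()
        comps, _ = compute_loss(raw, gt, ANCH, LossConfig(), 1, 64)
        assert comps.l_bbox >= 0 and comps.l_cfd >= 0 and comps.l_cls >= 0
        assert comps.total == comps.l_bbox + comps.l_cfd + comps.l_cls

    def test_seed_gradients_match_finite_differences(self):
        # constant-1 confidence targets: with IoU-valued targets the target
        # itself moves under perturbation (it is deliberately detached)
        raw, gt = self._setup()
        cfg = LossConfig(iou_objectness=False)
        comps, seeds = compute_loss(raw, gt, ANCH, cfg, 1, 64)
        rng = np.random.default_rng(0)

        def total():
            c, _ = compute_loss(raw, gt, ANCH, cfg, 1, 64)
            return c.total

        for s in range(3):
            for _ in range(6):
                i = tuple(rng.integers(0, d) for d in raw[s].data.shape)
                o = raw[s].data[i]
                raw[s].data[i] = o + 1e-6
                fp = total()
                raw[s].data[i] = o - 1e-6
                fm = total()
                raw[s].data[i] = o
                # abs tolerance covers the frozen-alpha CIoU convention
                assert (fp - fm) / 2e-6 == pytest.approx(seeds[s][i], abs=3e-4)

    def test_permutation_invariance_of_ground_truth_order(self):
        raw, gt = self._setup()
        c1, _ = compute_loss(raw, gt, ANCH, LossConfig(), 1, 64)
        gt_perm = [g[::-1].copy() for g in gt]
        c2, _ = compute_loss(raw, gt_perm, ANCH, LossConfig(), 1, 64)
        assert c1.total == pytest.approx(c2.total, rel=1e-12)

    def test_empty_ground_truth_gives_zero_box_and_class(self):
        raw, _ = self._setup()
        comps, _ = compute_loss(raw, [np.zeros((0, 5))] * 2, ANCH,
                                LossConfig(), 1, 64)
        assert comps.l_bbox == 0.0 and comps.l_cls == 0.0
        assert comps.l_cfd > 0.0
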
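"""Greedy matching, PR curves, AP and F1."""

import itertools

import numpy as np
import pytest

from bassdet.boxes import Annotation, Box, Detection, LabeledImage, ValidationError
from bassdet.evaluation import (
    evaluate_detections, f1_score, match_detections, pr_curve_and_ap,
)


def det(x0, y0, x1, y1, score):
    return Detection(Box.from_corners(x0, y0, x1, y1), score)


def ann(x0, y0, x1, y1):
    return Annotation(Box.from_corners(x0, y0, x1, y1))


def rectangle_sum_ap(flags, n_gt):
    """Brute-force area under the precision envelope."""
    if n_gt == 0 or not flags:
        return 0.0
    tp = np.cumsum(flags)
    prec = tp / np.arange(1, len(flags) + 1)
    rec = tp / n_gt
    # envelope at each recall point = max precision at >= that recall
    ap = 0.0
    r_prev = 0.0
    for i in range(len(flags)):
        env = max(prec[j] for j in range(len(flags)) if rec[j] >= rec[i])
        ap += (rec[i] - r_prev) * env
        r_prev = rec[i]
    return ap


class TestMatching:
    def test_perfect_detections_all_tp(self):
        gts = [ann(0, 0, 10, 10), ann(20, 20, 30, 30)]
        dets = [det(0, 0, 10, 10, 0.9), det(20, 20, 30, 30, 0.8)]
        flags, fn = match_detections(dets, gts)
        assert flags == [True, True] and fn == 0

    def test_no_detections_all_fn(self):
        flags, fn = match_detections([], [ann(0, 0, 5, 5)] * 3)
        assert flags == [] and fn == 3

    def test_double_detection_one_gt(self):
        """Two detections over one gt: higher score claims it, lower is FP —
        verified against exhaustive assignment over <= 5 boxes."""
        gts = [ann(0, 0, 10, 10)]
        dets = [det(0, 0, 10, 10, 0.6), det(1, 0, 11, 10, 0.9)]
        flags, fn = match_detections(dets, gts)
        # score order: 0.9 first
        assert flags == [True, False] and fn == 0

    def test_greedy_claims_highest_iou(self):
        gts = [ann(0, 0, 10, 10), ann(4, 0, 14, 10)]
        dets = [det(3, 0, 13, 10, 0.9)]
        flags, fn = match_detections(dets, gts)
        assert flags == [True] and fn == 1

    def test_invalid_threshold(self):
        with pytest.raises(ValidationError):
            match_detections([], [], iou_threshold=0.0)


class TestAP:
    def test_all_tp_gives_unity(self):
        rep = pr_curve_and_ap([True] * 4, 4)
        assert rep.ap50 == rep.precision == rep.recall == rep.f1 == 1.0

    def test_worked_ranked_list(self):
        """(TP, FP, TP) on 3 gt: PR points (1/3,1), (1/3,1/2), (2/3,2/3);
        AP = 1/3 * 1 + 1/3 * 2/3 = 5/9."""
        rep = pr_curve_and_ap([True, False, True], 3)
        assert rep.pr_curve == pytest.approx(
            [(1 / 3, 1.0), (1 / 3, 0.5), (2 / 3, 2 / 3)])
        assert rep.ap50 == pytest.approx(5 / 9)

    def test_matches_rectangle_sum_oracle_exhaustively(self):
        """All-point AP equals the brute-force envelope integral for every
        TP/FP pattern of length <= 8 and every plausible gt count."""
        for n in range(0, 9):
            for bits in itertools.product([False, True], repeat=n):
                tp = sum(bits)
                for n_gt in {max(tp, 1), tp + 1, tp + 3} - {0}:
                    got = pr_curve_and_ap(list(bits), n_gt).ap50
                    assert got == pytest.approx(rectangle_sum_ap(list(bits), n_gt),
                                                abs=1e-12)

    def test_trailing_fp_never_increases_ap(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            flags = list(rng.uniform(size=rng.integers(1, 8)) < 0.5)
            n_gt = max(sum(flags), 1) + int(rng.integers(0, 3))
            base = pr_curve_and_ap(flags, n_gt).ap50
            assert pr_curve_and_ap(flags + [False], n_gt).ap50 <= base + 1e-12

    def test_adding_tp_for_missed_gt_never_decreases_ap(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            flags = list(rng.uniform(size=rng.integers(1, 8)) < 0.5)
            n_gt = sum(flags) + 2
            base = pr_curve_and_ap(flags, n_gt).ap50
            assert pr_curve_and_ap(flags + [True], n_gt).ap50 >= base - 1e-12

    def test_no_gt_convention(self):
        rep = pr_curve_and_ap([False, False], 0)
        assert rep.ap50 == 0.0 and rep.recall_undefined

    def test_eleven_point_mode_close_to_all_point(self):
        flags = [True, True, False, True, False]
        a = pr_curve_and_ap(flags, 4, interpolation="all-point").ap50
        b = pr_curve_and_ap(flags, 4, interpolation="11-point").ap50
        assert 0 < b <= 1 and abs(a - b) < 0.25


class TestF1:
    def test_harmonic_mean_of_equals(self):
        assert f1_score(0.9, 0.9) == pytest.approx(0.9)

    def test_published_rows(self):
        """2PR/(P+R) on the two self-consistent published P/R rows."""
        assert f1_score(0.9734, 0.9533) == pytest.approx(0.9632, abs=5e-5)
        assert f1_score(0.9531, 0.9259) == pytest.approx(0.9393, abs=5e-5)

    def test_upper_bound_by_arithmetic_mean(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            p, r = rng.uniform(0.01, 1, 2)
            f1 = f1_score(p, r)
            assert f1 <= (p + r) / 2 + 1e-12
            if abs(p - r) > 1e-9:
                assert f1 < (p + r) / 2

    def test_degenerate_zero(self):
        assert f1_score(0.0, 0.0) == 0.0
        with pytest.raises(ValidationError):
            f1_score(1.2, 0.5)


class TestDatasetEvaluation:
    def _images(self):
        imgs = []
        for i in range(3):
            px = np.zeros((64, 64, 3), np.uint8)
            anns = [ann(5 + 10 * j, 5, 13 + 10 * j, 13) for j in range(i + 1)]
            imgs.append(LabeledImage(pixels=px, annotations=anns, source_id=str(i)))
        return imgs

    def test_oracle_detector_gives_ap_one(self):
        imgs = self._images()
        dets = [[Detection(a.box, 1.0) for a in im.annotations] for im in imgs]
        rep = evaluate_detections(dets, imgs)
        assert rep.ap50 == 1.0 and rep.fn == 0

    def test_empty_detector_gives_zero(self):
        imgs = self._images()
        rep = evaluate_detections([[] for _ in imgs], imgs)
        assert rep.ap50 == 0.0 and rep.recall == 0.0
        assert rep.fn == sum(len(im.annotations) for im in imgs)

    def test_report_invariants(self):
        imgs = self._images()
        dets = [[Detection(a.box, 0.9) for a in im.annotations[:1]] for im in imgs]
        rep = evaluate_detections(dets, imgs)
        assert 0 <= rep.ap50 <= 1 and 0 <= rep.f1 <= 1
        assert rep.tp + rep.fn == sum(len(im.annotations) for im in imgs)
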
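"""Detection scoring: greedy matching at IoU 0.5, precision/recall, AP, F1.

    P  = TP / (TP + FP)          R = TP / (TP + FN)
    AP = area under the P(R) curve (all-point interpolation by default)
    F1 = 2 P R / (P + R)

Detections are ranked by descending score; each claims the unclaimed
ground-truth box of highest IoU at or above the threshold (a true
positive) or counts as a false positive.  Unclaimed ground truth are false
negatives.  AP integrates the precision envelope over recall; an 11-point
interpolation mode is available for comparison with older protocols.  The
summary F1 operating point is the score threshold that maximizes F1 on the
ranked list.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .boxes import Detection, LabeledImage, ValidationError
from .losses import iou_matrix

logger = logging.getLogger(__name__)

__all__ = ["EvalReport", "match_detections", "pr_curve_and_ap", "f1_score",
           "evaluate_detections", "evaluate_model"]


@dataclass
class EvalReport:
    """Aggregate detection quality over a dataset."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    ap50: float
    f1: float
    pr_curve: list[tuple[float, float]] = field(default_factory=list)
    recall_undefined: bool = False

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("tp", "fp", "fn", "precision", "recall", "ap50", "f1", "recall_undefined")}
        return d

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_pr_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["recall", "precision"])
            w.writerows(self.pr_curve)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 (with a warning) at P=R=0."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1], got {v}")
    if precision == 0.0 and recall == 0.0:
        logger.warning("F1 undefined at P=R=0; returning 0")
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _det_sort_key(d: Detection):
    x0, y0, x1, y1 = d.box.corners
    return (-d.score, x0, y0, x1, y1)


def match_detections(detections: list[Detection], ground_truth: list,
                     iou_threshold: float = 0.5) -> tuple[list[bool], int]:
    """Greedy one-to-one matching of score-ranked detections to ground truth.

    ``ground_truth`` is a list of :class:`~bassdet.boxes.Annotation` (or
    anything with a ``.box``).  Returns per-detection TP flags in score
    order plus the count of unmatched ground truth (FN).
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise ValidationError(f"iou_threshold must lie in (0, 1], got {iou_threshold}")
    dets = sorted(detections, key=_det_sort_key)
    flags: list[bool] = []
    claimed = [False] * len(ground_truth)
    if ground_truth and dets:
        g = np.array([gt.box.corners for gt in ground_truth])
        d = np.array([det.box.corners for det in dets])
        ious = iou_matrix(d, g)
    for i, det in enumerate(dets):
        best_j, best_iou = -1, iou_threshold
        for j, gt in enumerate(ground_truth):
            if claimed[j]:
                continue
            v = ious[i, j]
            if v >= best_iou and (best_j < 0 or v > best_iou):
                best_j, best_iou = j, v
        if best_j >= 0:
            claimed[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    fn = claimed.count(False)
    return flags, fn


def pr_curve_and_ap(flags: list[bool], n_gt: int, *, scores: list[float] | None = None,
                    interpolation: str = "all-point") -> EvalReport:
    """Cumulative precision/recall over a score-ranked TP/FP list, and AP.

    ``interpolation``: ``'all-point'`` integrates the precision envelope
    (modern VOC/COCO convention); ``'11-point'`` averages the envelope at
    recalls 0.0, 0.1, ..., 1.0.  With ``n_gt == 0`` recall is undefined and
    AP is reported as 0 by convention.
    """
    if n_gt < 0:
        raise ValidationError("n_gt must be >= 0")
    flags = [bool(f) for f in flags]
    tp_cum = np.cumsum(flags) if flags else np.array([], dtype=float)
    n = len(flags)
    precision = tp_cum / np.arange(1, n + 1) if n else np.array([])
    if n_gt == 0:
        rep = EvalReport(tp=0, fp=n, fn=0, precision=0.0 if n else 1.0,
                         recall=0.0, ap50=0.0, f1=0.0, recall_undefined=True)
        rep.pr_curve = [(0.0, float(p)) for p in precision]
        return rep
    recall = tp_cum / n_gt if n else np.array([])

    if n:
        # precision envelope: running max from the right
        env = np.maximum.accumulate(precision[::-1])[::-1]
        if interpolation == "all-point":
            r_prev = 0.0
            ap = 0.0
            for i in range(n):
                ap += (recall[i] - r_prev) * env[i]
                r_prev = recall[i]
        elif interpolation == "11-point":
            ap = 0.0
            for r in np.linspace(0, 1, 11):
                mask = recall >= r - 1e-12
                ap += (env[mask].max() if mask.any() else 0.0) / 11
        else:
            raise ValidationError(f"unknown interpolation {interpolation!r}")
    else:
        ap = 0.0

    tp = int(tp_cum[-1]) if n else 0
    fp = n - tp
    fn = n_gt - tp
    # summary operating point: the rank cut maximizing F1
    best_f1, best_p, best_r = 0.0, (1.0 if n == 0 else float(precision[0])), 0.0
    for i in range(n):
        p, r = float(precision[i]), float(recall[i])
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        if f1 > best_f1:
            best_f1, best_p, best_r = f1, p, r
    if scores is not None and len(scores) != n:
        raise ValidationError("scores length must match flags")
    rep = EvalReport(tp=tp, fp=fp, fn=fn,
                     precision=best_p, recall=best_r, ap50=float(ap),
                     f1=best_f1)
    rep.pr_curve = [(float(r), float(p)) for r, p in zip(recall, precision)]
    return rep


def evaluate_detections(per_image_detections: list[list[Detection]],
                        images: list[LabeledImage],
                        iou_threshold: float = 0.5,
                        interpolation: str = "all-point") -> EvalReport:
    """Score detections against ground truth across a dataset."""
    if len(per_image_detections) != len(images):
        raise ValidationError("detections and images must align")
    records: list[tuple[float, bool]] = []
    n_gt = 0
    for dets, img in zip(per_image_detections, images):
        flags, _ = match_detections(dets, img.annotations, iou_threshold)
        ranked = sorted(dets, key=_det_sort_key)
        records.extend((d.score, f) for d, f in zip(ranked, flags))
        n_gt += len(img.annotations)
    records.sort(key=lambda t: -t[0])
    return pr_curve_and_ap([f for _, f in records], n_gt,
                           interpolation=interpolation)


def scale_to_input(images: list[LabeledImage], input_size: int) -> list[LabeledImage]:
    """Re-express ground-truth boxes in model-input pixel coordinates."""
    from .boxes import Annotation, Box

    out = []
    for im in images:
        W, H = im.size
        if (W, H) == (input_size, input_size):
            out.append(im)
            continue
        anns = []
        for ann in im.annotations:
            b = ann.box.to_pixel((W, H))
            anns.append(Annotation(Box(b.cx * input_size / W, b.cy * input_size / H,
                                       b.w * input_size / W, b.h * input_size / H),
                                   ann.class_name, ann.difficult))
        out.append(LabeledImage(pixels=im.pixels, annotations=anns,
                                source_id=im.source_id))
    return out


def evaluate_model(model, dataset: list[LabeledImage], suppression_config,
                   iou_threshold: float = 0.5,
                   conf_threshold: float = 0.001,
                   batch_size: int = 8) -> EvalReport:
    """Run inference + suppression + matching over a labeled dataset."""
    from .inference import detect_images

    if not dataset:
        raise ValidationError("cannot evaluate on an empty dataset")
    dataset = scale_to_input(dataset, model.config.input_size)
    dets = detect_images(model, dataset, suppression_config,
                         conf_threshold=conf_threshold, batch_size=batch_size)
    return evaluate_detections(dets, dataset, iou_threshold)
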
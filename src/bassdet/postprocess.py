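"""Prediction-box re-screening: classical NMS and linear Soft-NMS.

Classical NMS greedily takes the highest-scoring box and zeroes every
remaining box that overlaps it beyond the threshold ``N_j``; in dense
scenes this deletes true neighbors and causes missed detections.  Linear
Soft-NMS instead decays the overlapping scores,

    s_k <- s_k * (1 - IoU(M, b_k))    when IoU(M, b_k) > N_j,

keeping heavily-overlapped true positives alive for the next screening
round.  Both run per class; ties are broken deterministically by score,
then area, then coordinates, so the output is invariant to input order.

The published formulation prints the two inequalities transposed relative
to the original NMS/Soft-NMS definitions (and to its own prose); the
standard orientation — suppress/decay when the overlap is HIGH — is the
default here, with ``strict_paper_mode`` retaining the printed orientation
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

from .boxes import Detection, ValidationError
from .losses import iou

__all__ = ["SuppressionConfig", "nms", "soft_nms", "suppress", "count_fish"]


@dataclass(frozen=True)
class SuppressionConfig:
    """``nj`` is the overlap threshold; rescored boxes below
    ``final_score_min`` are discarded."""

    nj: float = 0.5
    final_score_min: float = 0.001
    method: str = "soft-nms"            # "nms" | "soft-nms"
    strict_paper_mode: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.nj <= 1.0):
            raise ValidationError(f"nj must lie in [0, 1], got {self.nj}")
        if not (0.0 <= self.final_score_min < 1.0):
            raise ValidationError("final_score_min must lie in [0, 1)")
        if self.method not in ("nms", "soft-nms"):
            raise ValidationError(f"unknown suppression method {self.method!r}")


def _sort_key(d: Detection):
    x0, y0, x1, y1 = d.box.corners
    return (-d.score, -d.box.area, x0, y0, x1, y1)


def _greedy(detections: list[Detection], config: SuppressionConfig,
            soft: bool) -> list[Detection]:
    pending = [Detection(d.box, d.score, d.class_index) for d in detections]
    kept: list[Detection] = []
    while pending:
        pending.sort(key=_sort_key)
        m = pending.pop(0)
        if m.score < config.final_score_min or m.score <= 0:
            break
        kept.append(m)
        survivors = []
        for d in pending:
            if d.class_index != m.class_index:
                survivors.append(d)
                continue
            overlap = iou(m.box, d.box)
            high = overlap >= config.nj
            if config.strict_paper_mode:
                # printed orientation: act on LOW overlap instead
                high = not high
            if high:
                d.score = 0.0 if not soft else d.score * (1.0 - overlap)
            if d.score >= config.final_score_min and d.score > 0:
                survivors.append(d)
        pending = survivors
    return kept


def nms(detections: list[Detection], config: SuppressionConfig) -> list[Detection]:
    """Greedy hard suppression; survivors keep their original scores."""
    return _greedy(detections, config, soft=False)


def soft_nms(detections: list[Detection], config: SuppressionConfig) -> list[Detection]:
    """Greedy linear score decay; never increases any score."""
    return _greedy(detections, config, soft=True)


def suppress(detections: list[Detection], config: SuppressionConfig) -> list[Detection]:
    """Dispatch on ``config.method``."""
    return soft_nms(detections, config) if config.method == "soft-nms" else nms(detections, config)


def count_fish(detections: list[Detection], config: SuppressionConfig,
               class_index: int = 0) -> int:
    """Number of retained detections of the fish class at the final threshold."""
    return sum(1 for d in detections
               if d.class_index == class_index and d.score >= config.final_score_min)
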
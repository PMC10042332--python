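"""Prior-box generation by k-means clustering of ground-truth box sizes.

Boxes are clustered as origin-aligned ``(w, h)`` rectangles under the
distance ``d = 1 - IoU`` (the YOLO convention: two sizes are close when the
smaller rectangle covers most of the larger one, irrespective of position).
Lloyd iterations with k-means++ seeding and multiple restarts; cluster
centers are the medoid-free component-wise means of their members.

The nine resulting priors are sorted by area and partitioned 3/3/3 across
the three prediction scales (smallest-area triplet to the highest-resolution
head, stride 8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes import ValidationError

__all__ = ["AnchorSet", "kmeans_anchors", "assign_anchor_scales", "iou_wh"]

STRIDES = (8, 16, 32)


@dataclass(frozen=True)
class AnchorSet:
    """Nine (w, h) priors partitioned into three per-scale triplets."""

    anchors: tuple[tuple[float, float], ...]
    scale_groups: tuple[tuple[int, int, int], ...] = field(default=((0, 1, 2), (3, 4, 5), (6, 7, 8)))

    def __post_init__(self) -> None:
        if len(self.anchors) != 9:
            raise ValidationError(f"need exactly 9 anchors, got {len(self.anchors)}")
        if any(w <= 0 or h <= 0 for w, h in self.anchors):
            raise ValidationError("anchor dimensions must be positive")
        flat = [i for g in self.scale_groups for i in g]
        if sorted(flat) != list(range(9)) or len(self.scale_groups) != 3:
            raise ValidationError("scale_groups must be a 3x3 partition of 0..8")

    def per_scale(self) -> list[np.ndarray]:
        """[(3, 2) arrays] of (w, h) priors for strides 8, 16, 32."""
        return [np.array([self.anchors[i] for i in g], dtype=np.float64)
                for g in self.scale_groups]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.anchors, dtype=np.float64)

    def scaled(self, factor: float) -> "AnchorSet":
        return AnchorSet(tuple((w * factor, h * factor) for w, h in self.anchors),
                         self.scale_groups)


#: priors published for the authors' tank dataset (w, h at 640 input)
DEFAULT_ANCHORS = AnchorSet(
    anchors=((12, 72), (46, 27), (16, 81), (21, 76), (44, 39), (28, 63),
             (20, 97), (41, 58), (35, 79)),
)


def iou_wh(wh: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Pairwise IoU of origin-aligned rectangles, shape (n, k)."""
    wh = np.atleast_2d(np.asarray(wh, dtype=np.float64))
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    inter = (np.minimum(wh[:, None, 0], centers[None, :, 0])
             * np.minimum(wh[:, None, 1], centers[None, :, 1]))
    union = (wh[:, 0] * wh[:, 1])[:, None] + (centers[:, 0] * centers[:, 1])[None, :] - inter
    return inter / union


def _plus_plus_init(wh: np.ndarray, k: int, rng: np.random.Generator,
                    metric: str) -> np.ndarray:
    centers = [wh[rng.integers(len(wh))]]
    for _ in range(1, k):
        d = _distances(wh, np.array(centers), metric).min(axis=1)
        probs = d / d.sum() if d.sum() > 0 else np.full(len(wh), 1 / len(wh))
        centers.append(wh[rng.choice(len(wh), p=probs)])
    return np.array(centers)


def _distances(wh: np.ndarray, centers: np.ndarray, metric: str) -> np.ndarray:
    if metric == "iou":
        return 1.0 - iou_wh(wh, centers)
    if metric == "euclidean":
        return np.linalg.norm(wh[:, None, :] - centers[None, :, :], axis=2)
    raise ValidationError(f"unknown metric {metric!r}")


def _lloyd(wh: np.ndarray, centers: np.ndarray, metric: str,
           max_iter: int = 300) -> tuple[np.ndarray, float]:
    """Lloyd iterations with a monotonicity guard.

    Under the 1 - IoU distance the component-wise mean is only a heuristic
    center update (it need not minimize the within-cluster distance), so a
    proposed update is accepted only when it lowers the objective; the
    objective sequence is therefore non-increasing by construction and the
    iteration stops at the first non-improving update.
    """
    prev_obj = _distances(wh, centers, metric).min(axis=1).mean()
    for _ in range(max_iter):
        d = _distances(wh, centers, metric)
        labels = d.argmin(axis=1)
        proposal = centers.copy()
        for j in range(len(centers)):
            members = wh[labels == j]
            if len(members):
                proposal[j] = members.mean(axis=0)
        obj = _distances(wh, proposal, metric).min(axis=1).mean()
        if obj >= prev_obj - 1e-12:
            break
        centers, prev_obj = proposal, obj
    return centers, prev_obj


def kmeans_anchors(boxes: np.ndarray, k: int = 9, seed: int = 0,
                   restarts: int = 10, metric: str = "iou") -> AnchorSet:
    """Cluster (w, h) pairs into ``k`` prior boxes; best of ``restarts`` runs.

    Parameters
    ----------
    boxes:
        (n, 2) array of positive (w, h) pairs in pixels at the reference
        input resolution.
    metric:
        ``'iou'`` (1 - IoU of origin-aligned rectangles, default) or
        ``'euclidean'``.
    """
    if k != 9:
        raise ValidationError("AnchorSet requires k=9; use kmeans_centers for other k")
    centers, _ = kmeans_centers(boxes, k, seed=seed, restarts=restarts, metric=metric)
    return assign_anchor_scales_from_centers(centers)


def kmeans_centers(boxes: np.ndarray, k: int, seed: int = 0, restarts: int = 10,
                   metric: str = "iou") -> tuple[np.ndarray, float]:
    """Like :func:`kmeans_anchors` for arbitrary ``k``: (centers, objective)."""
    wh = np.asarray(boxes, dtype=np.float64).reshape(-1, 2)
    if len(wh) < k:
        raise ValidationError(f"need at least k={k} boxes, got {len(wh)}")
    if (wh <= 0).any():
        raise ValidationError("all box dimensions must be positive")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        centers, obj = _lloyd(wh, _plus_plus_init(wh, k, rng, metric).copy(), metric)
        if best is None or obj < best[1]:
            best = (centers, obj)
    assert best is not None
    order = np.lexsort((best[0][:, 1], best[0][:, 0], best[0].prod(axis=1)))
    return best[0][order], best[1]


def assign_anchor_scales_from_centers(centers: np.ndarray) -> AnchorSet:
    """Sort 9 centers by area (ties by w then h) and partition 3/3/3."""
    centers = np.asarray(centers, dtype=np.float64).reshape(9, 2)
    order = np.lexsort((centers[:, 1], centers[:, 0], centers.prod(axis=1)))
    ordered = centers[order]
    return AnchorSet(anchors=tuple((float(w), float(h)) for w, h in ordered))


def assign_anchor_scales(anchors: AnchorSet) -> AnchorSet:
    """Re-sort an anchor set by area and assign scale groups P3/P4/P5."""
    return assign_anchor_scales_from_centers(anchors.as_array())
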
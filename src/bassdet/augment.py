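"""Mosaic-8 augmentation and photometric jitter.

Mosaic-8 composites eight independently scaled-and-cropped labeled images
onto a single canvas in a 4x2 cell layout with jittered cell boundaries,
carrying every ground-truth box through the same affine placement as its
pixels.  Boxes that are clipped down to slivers are dropped.  Random
brightness and additive Gaussian noise provide photometric variety.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boxes import Annotation, Box, LabeledImage, ValidationError

__all__ = ["AugmentConfig", "mosaic8", "adjust_brightness", "add_gaussian_noise",
           "resize_image", "flip_labeled"]


@dataclass(frozen=True)
class AugmentConfig:
    """Knobs of the augmentation pipeline (all randomness via ``seed``)."""

    mosaic8_prob: float = 0.5
    flip_prob: float = 0.5            # per-axis mirror probability
    brightness_range: tuple[float, float] = (0.7, 1.3)
    noise_sigma_range: tuple[float, float] = (0.0, 6.0)
    min_box_area_px: float = 8.0
    min_box_area_frac: float = 0.2      # of the original box area
    canvas_size: int = 640
    cell_jitter: float = 0.2            # fraction of cell size
    scale_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mosaic8_prob <= 1.0):
            raise ValidationError("mosaic8_prob must lie in [0, 1]")
        if self.min_box_area_px < 0 or self.min_box_area_frac < 0:
            raise ValidationError("box-drop thresholds must be nonnegative")


def adjust_brightness(image: np.ndarray, factor: float) -> np.ndarray:
    """Scale every channel by ``factor`` and clip to [0, 255]."""
    if factor <= 0:
        raise ValidationError(f"brightness factor must be positive, got {factor}")
    out = np.clip(image.astype(np.float64) * factor, 0, 255)
    return np.rint(out).astype(np.uint8)


def add_gaussian_noise(image: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Additive per-pixel Gaussian noise, clipped to [0, 255]."""
    if sigma < 0:
        raise ValidationError(f"noise sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    out = image.astype(np.float64) + rng.normal(0.0, sigma, size=image.shape)
    return np.rint(np.clip(out, 0, 255)).astype(np.uint8)


def resize_image(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resize to (W, H) — cheap and label-exact for scaling."""
    W, H = size
    h0, w0 = image.shape[:2]
    rows = np.clip(((np.arange(H) + 0.5) * h0 / H).astype(int), 0, h0 - 1)
    cols = np.clip(((np.arange(W) + 0.5) * w0 / W).astype(int), 0, w0 - 1)
    return image[rows][:, cols]


def flip_labeled(image: LabeledImage, horizontal: bool = False,
                 vertical: bool = False) -> LabeledImage:
    """Mirror an image (and its boxes) along the chosen axes.

    Top-view tank scenes are statistically mirror-symmetric, which makes
    flips a label-exact augmentation.
    """
    if image.pixels is None:
        raise ValidationError("flip_labeled needs pixel data")
    px = image.pixels
    W, H = image.size
    if horizontal:
        px = px[:, ::-1]
    if vertical:
        px = px[::-1]
    anns = []
    for ann in image.annotations:
        b = ann.box.to_pixel((W, H))
        cx = W - b.cx if horizontal else b.cx
        cy = H - b.cy if vertical else b.cy
        anns.append(Annotation(Box(cx, cy, b.w, b.h), ann.class_name, ann.difficult))
    return LabeledImage(pixels=np.ascontiguousarray(px), annotations=anns,
                        source_id=image.source_id)


def _cell_edges(total: int, n: int, jitter: float, rng: np.random.Generator) -> np.ndarray:
    """n+1 monotone edges over [0, total] with jittered interior boundaries."""
    edges = np.linspace(0, total, n + 1)
    cell = total / n
    for i in range(1, n):
        edges[i] += rng.uniform(-jitter, jitter) * cell
    return np.rint(np.sort(edges)).astype(int)


def mosaic8(images: Sequence[LabeledImage], config: AugmentConfig) -> LabeledImage:
    """Composite exactly eight labeled images onto one canvas (4x2 cells).

    Each source image is randomly scaled, then a random crop of it fills its
    cell; ground-truth boxes follow the same scale-and-shift affine map, are
    clipped to the cell, and dropped when the clipped area falls below
    ``min_box_area_px`` or ``min_box_area_frac`` of the transformed box.
    Deterministic given ``config.seed``.
    """
    if len(images) != 8:
        raise ValidationError(f"mosaic8 needs exactly 8 images, got {len(images)}")
    rng = np.random.default_rng(config.seed)
    S = config.canvas_size
    canvas = np.zeros((S, S, 3), dtype=np.uint8)
    xs = _cell_edges(S, 4, config.cell_jitter, rng)
    ys = _cell_edges(S, 2, config.cell_jitter, rng)

    out_annotations: list[Annotation] = []
    k = 0
    for row in range(2):
        for col in range(4):
            src = images[k]
            k += 1
            if src.pixels is None:
                raise ValidationError("mosaic8 needs pixel data for every image")
            cw, ch = xs[col + 1] - xs[col], ys[row + 1] - ys[row]
            if cw <= 0 or ch <= 0:
                continue
            scale = rng.uniform(*config.scale_range)
            w0, h0 = src.size
            sw, sh = max(1, round(w0 * scale)), max(1, round(h0 * scale))
            scaled = resize_image(src.pixels, (sw, sh))
            # random crop window of the scaled image, padded if too small
            ox = rng.integers(0, max(1, sw - cw + 1))
            oy = rng.integers(0, max(1, sh - ch + 1))
            crop = scaled[oy:oy + ch, ox:ox + cw]
            canvas[ys[row]:ys[row] + crop.shape[0], xs[col]:xs[col] + crop.shape[1]] = crop

            # affine map: p_canvas = p_src * scale_eff - (ox, oy) + cell origin
            sx, sy = sw / w0, sh / h0
            for ann in src.annotations:
                b = ann.box.to_pixel(src.size)
                x0, y0, x1, y1 = b.corners
                x0, x1 = x0 * sx - ox + xs[col], x1 * sx - ox + xs[col]
                y0, y1 = y0 * sy - oy + ys[row], y1 * sy - oy + ys[row]
                full_area = (x1 - x0) * (y1 - y0)
                # clip to the visible cell region
                cx0, cy0 = xs[col], ys[row]
                cx1, cy1 = xs[col] + crop.shape[1], ys[row] + crop.shape[0]
                x0c, x1c = max(x0, cx0), min(x1, cx1)
                y0c, y1c = max(y0, cy0), min(y1, cy1)
                if x1c - x0c <= 0 or y1c - y0c <= 0:
                    continue
                area = (x1c - x0c) * (y1c - y0c)
                if area < config.min_box_area_px or area < config.min_box_area_frac * full_area:
                    continue
                out_annotations.append(Annotation(
                    box=Box.from_corners(x0c, y0c, x1c, y1c),
                    class_name=ann.class_name, difficult=ann.difficult,
                ))

    return LabeledImage(pixels=canvas, annotations=out_annotations, source_id="mosaic8")
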
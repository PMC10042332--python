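"""Synthetic top-view tank scenes with ground-truth boxes.

Emulates overhead captures of a circular recirculating-aquaculture tank:
a dark circular pond on a darker floor, with ellipse-bodied fish (plus a
triangular tail) at random positions and orientations.  Overlap/occlusion
between fish — the failure mode that motivates attention and soft
suppression in the detector — is controllable: pairs of fish can be forced
to overlap side-by-side (``parallel``), crossing (``cross``), or the whole
tank can simply be packed (``dense``).

Every scene is fully reproducible from its integer seed; the emitted
bounding boxes are the tight axis-aligned bounds of the rendered fish
silhouettes, measured before photometric noise is applied.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .boxes import Annotation, Box, LabeledImage, ValidationError, write_voc_xml, write_yolo_txt

__all__ = [
    "SceneConfig", "PlacementError", "generate_scene", "generate_dataset",
    "TINY_PRESET", "EASY_PRESET",
]


class PlacementError(RuntimeError):
    """Could not place the requested fish within the attempt budget."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(f"placed {achieved} of {requested} fish within the attempt budget")
        self.requested = requested
        self.achieved = achieved


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic tank scene.

    Lengths are in pixels at ``image_size``; ``brightness_factor`` and
    ``noise_sigma`` are sampled uniformly from their ranges per scene.
    """

    image_size: tuple[int, int] = (640, 640)
    n_fish: int = 8
    fish_length_range: tuple[float, float] = (110.0, 180.0)
    aspect_range: tuple[float, float] = (3.0, 4.5)
    occlusion_mode: str = "none"          # none | parallel | cross | dense
    min_pair_iou: float = 0.2
    brightness_factor: tuple[float, float] = (1.0, 1.0)
    noise_sigma: tuple[float, float] = (0.0, 0.0)
    tank_margin: float = 0.04
    seed: int = 0
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.n_fish < 0:
            raise ValidationError("n_fish must be >= 0")
        for name in ("fish_length_range", "aspect_range", "brightness_factor", "noise_sigma"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} has low > high: ({lo}, {hi})")
        if not (0.0 <= self.min_pair_iou < 1.0):
            raise ValidationError("min_pair_iou must lie in [0, 1)")
        if self.occlusion_mode not in ("none", "parallel", "cross", "dense"):
            raise ValidationError(f"unknown occlusion_mode {self.occlusion_mode!r}")

    def replace(self, **kwargs) -> "SceneConfig":
        return dataclasses.replace(self, **kwargs)


#: 160x160 preset for CPU smoke tests (fish scaled with the canvas)
TINY_PRESET = SceneConfig(
    image_size=(160, 160), n_fish=5,
    fish_length_range=(28.0, 44.0), aspect_range=(3.0, 4.0),
)

#: uncluttered, high-contrast scenes used by the training smoke tests
EASY_PRESET = SceneConfig(
    image_size=(160, 160), n_fish=4,
    fish_length_range=(30.0, 44.0), aspect_range=(3.0, 3.8),
    occlusion_mode="none", noise_sigma=(0.0, 2.0),
)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_FLOOR_GRAY = 26.0
_TANK_GRAY = 64.0
_FISH_GRAY = 185.0


def _fish_mask(W: int, H: int, cx: float, cy: float, length: float,
               width: float, theta: float) -> np.ndarray:
    """Boolean silhouette of one fish: ellipse torso plus triangular tail."""
    half = length / 2
    # local window around the fish to keep the mask computation cheap
    r = int(np.ceil(half + width)) + 2
    x0, x1 = max(0, int(cx) - r), min(W, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(H, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return np.zeros((H, W), dtype=bool)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    # pixel centers at integer+0.5 in the continuous frame
    dx = xs + 0.5 - cx
    dy = ys + 0.5 - cy
    c, s = np.cos(theta), np.sin(theta)
    u = c * dx + s * dy          # along body axis
    v = -s * dx + c * dy         # across body axis
    a = 0.72 * half              # torso semi-major (leaves room for the tail)
    b = width / 2
    torso = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    # tail: triangle from the torso rear (-0.5a) flaring back to -half
    tail_len = half - 0.5 * a
    t = (-u - 0.5 * a) / tail_len           # 0 at torso rear, 1 at tail tip
    tail = (t >= 0) & (t <= 1) & (np.abs(v) <= b * (0.25 + 0.75 * t))
    local = torso | tail
    mask = np.zeros((H, W), dtype=bool)
    mask[y0:y1, x0:x1] = local
    return mask


def _tight_box(mask: np.ndarray) -> Box:
    ys, xs = np.nonzero(mask)
    # half-open pixel-index extent of the silhouette
    return Box.from_corners(float(xs.min()), float(ys.min()),
                            float(xs.max() + 1), float(ys.max() + 1))


def _pair_iou(a: Box, b: Box) -> float:
    ax0, ay0, ax1, ay1 = a.corners
    bx0, by0, bx1, by1 = b.corners
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


@dataclass
class _Fish:
    cx: float
    cy: float
    length: float
    width: float
    theta: float
    mask: np.ndarray
    box: Box


def _sample_fish(rng: np.random.Generator, cfg: SceneConfig,
                 at: tuple[float, float] | None = None,
                 theta: float | None = None) -> _Fish:
    W, H = cfg.image_size
    tank_r = min(W, H) / 2 * (1 - cfg.tank_margin)
    length = rng.uniform(*cfg.fish_length_range)
    aspect = rng.uniform(*cfg.aspect_range)
    width = length / aspect
    if theta is None:
        theta = rng.uniform(0, np.pi)
    if at is None:
        # keep the whole body inside the tank disc
        rad = (tank_r - length / 2) * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        at = (W / 2 + rad * np.cos(phi), H / 2 + rad * np.sin(phi))
    mask = _fish_mask(W, H, at[0], at[1], length, width, theta)
    if not mask.any():
        raise PlacementError(1, 0)
    return _Fish(at[0], at[1], length, width, theta, mask, _tight_box(mask))


def _place_fish(rng: np.random.Generator, cfg: SceneConfig) -> list[_Fish]:
    """Rejection-sample fish positions according to the occlusion mode."""
    placed: list[_Fish] = []

    def disjoint(f: _Fish) -> bool:
        return all(_pair_iou(f.box, g.box) == 0.0 for g in placed)

    if cfg.occlusion_mode in ("none", "dense"):
        for _ in range(cfg.n_fish):
            for attempt in range(cfg.max_attempts):
                f = _sample_fish(rng, cfg)
                if cfg.occlusion_mode == "dense" or disjoint(f):
                    placed.append(f)
                    break
            else:
                raise PlacementError(cfg.n_fish, len(placed))
        return placed

    # parallel / cross: floor(n/2) overlapping pairs (+ one single if odd)
    n_pairs, odd = divmod(cfg.n_fish, 2)
    for _ in range(n_pairs):
        for attempt in range(cfg.max_attempts):
            a = _sample_fish(rng, cfg)
            if not disjoint(a):
                continue
            if cfg.occlusion_mode == "parallel":
                theta_b = a.theta + rng.normal(0, 0.06)
                # offset sideways, slightly along-body
                off = rng.uniform(0.5, 0.9) * a.width
                along = rng.uniform(-0.15, 0.15) * a.length
                dx = -np.sin(a.theta) * off + np.cos(a.theta) * along
                dy = np.cos(a.theta) * off + np.sin(a.theta) * along
            else:  # cross
                theta_b = a.theta + np.pi / 2 + rng.normal(0, 0.1)
                dx = rng.uniform(-0.15, 0.15) * a.length
                dy = rng.uniform(-0.15, 0.15) * a.length
            try:
                b = _sample_fish(rng, cfg, at=(a.cx + dx, a.cy + dy), theta=theta_b)
            except PlacementError:
                continue
            if _pair_iou(a.box, b.box) >= cfg.min_pair_iou and disjoint(b):
                placed.extend([a, b])
                break
        else:
            raise PlacementError(cfg.n_fish, len(placed))
    if odd:
        for attempt in range(cfg.max_attempts):
            f = _sample_fish(rng, cfg)
            if disjoint(f):
                placed.append(f)
                break
        else:
            raise PlacementError(cfg.n_fish, len(placed))
    return placed


def generate_scene(config: SceneConfig, source_id: str = "scene") -> LabeledImage:
    """Render one tank scene; deterministic in ``config`` (including seed)."""
    rng = np.random.default_rng(config.seed)
    W, H = config.image_size
    img = np.full((H, W), _FLOOR_GRAY, dtype=np.float64)
    ys, xs = np.mgrid[0:H, 0:W]
    tank_r = min(W, H) / 2 * (1 - config.tank_margin)
    tank = (xs + 0.5 - W / 2) ** 2 + (ys + 0.5 - H / 2) ** 2 <= tank_r ** 2
    img[tank] = _TANK_GRAY
    # gentle radial shading so the tank is not perfectly uniform
    shade = 1.0 - 0.15 * np.sqrt(((xs + 0.5 - W / 2) ** 2 + (ys + 0.5 - H / 2) ** 2)) / tank_r
    img[tank] *= shade[tank]

    fish = _place_fish(rng, config)
    annotations = []
    for f in fish:
        gray = _FISH_GRAY + rng.uniform(-25, 25)
        img[f.mask] = gray
        # darker dorsal stripe along the body for some internal structure
        stripe = _fish_mask(W, H, f.cx, f.cy, f.length * 0.8, f.width * 0.3, f.theta)
        img[stripe & f.mask] = gray * 0.72
        annotations.append(Annotation(box=f.box, class_name="fish"))

    rgb = np.repeat(img[:, :, None], 3, axis=2)
    factor = rng.uniform(*config.brightness_factor)
    rgb = rgb * factor
    sigma = rng.uniform(*config.noise_sigma)
    if sigma > 0:
        rgb = rgb + rng.normal(0.0, sigma, size=rgb.shape)
    pixels = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return LabeledImage(pixels=pixels, annotations=annotations, source_id=source_id)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _child_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-image seeds derived from the master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n) & 0x7FFFFFFF


def generate_dataset(config: SceneConfig, n_images: int, out_dir: str | Path,
                     split: Sequence[float] = (0.8, 0.1, 0.1),
                     annotation_format: str = "xml") -> dict[str, int]:
    """Write ``n_images`` scenes under ``out_dir`` in the images/labels layout.

    Returns the number of images written per split.  Re-running with the same
    master seed reproduces identical file contents.
    """
    from PIL import Image

    if abs(sum(split) - 1.0) > 1e-9:
        raise ValidationError(f"split fractions must sum to 1, got {split}")
    out_dir = Path(out_dir)
    split_names = ("train", "val", "test")[: len(split)]
    # largest-remainder apportionment of n_images across splits
    raw = [f * n_images for f in split]
    counts = [int(np.floor(r)) for r in raw]
    rem = n_images - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for j in range(rem):
        counts[order[j]] += 1

    seeds = _child_seeds(config.seed, n_images)
    written = {}
    idx = 0
    for name, count in zip(split_names, counts):
        img_dir = out_dir / name / "images"
        lbl_dir = out_dir / name / "labels"
        try:
            img_dir.mkdir(parents=True, exist_ok=True)
            lbl_dir.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise IOError(f"cannot create dataset directory under {out_dir}: {exc}") from exc
        for _ in range(count):
            stem = f"scene_{idx:05d}"
            scene = generate_scene(config.replace(seed=int(seeds[idx])), source_id=stem)
            Image.fromarray(scene.pixels).save(img_dir / f"{stem}.png")
            if annotation_format == "xml":
                write_voc_xml(scene, lbl_dir / f"{stem}.xml")
            elif annotation_format == "txt":
                write_yolo_txt(scene, lbl_dir / f"{stem}.txt")
            else:
                raise ValidationError(f"unknown annotation_format {annotation_format!r}")
            idx += 1
        written[name] = count
    return written
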
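"""The detection network: CSP backbone (Focus stem, C3/C3CA, SPPF),
FPN+PAN neck with optional coordinate attention, three anchor-based heads.

Architecture summary (channel widths before the width multiple):

==========  ====================================  ======
stage       block                                 stride
==========  ====================================  ======
stem        Focus 3 -> 64                         2
backbone    Conv 128 / C3 n=3                     4
            Conv 256 / C3 n=6                     8   (P3 tap)
            Conv 512 / C3 n=9                     16  (P4 tap)
            Conv 1024 / C3 n=3 / SPPF             32
neck        FPN top-down + PAN bottom-up fusions  8/16/32
heads       1x1 convs to 3 * (5 + num_classes)    8/16/32
==========  ====================================  ======

With ``ca_sites`` containing ``"backbone_c3"`` the four backbone C3 blocks
become C3CA; with ``"neck"`` a standalone coordinate-attention unit follows
each of the four neck fusion C3 blocks.

Raw head outputs are decoded with the usual bounded parameterization:
``center = (2*sigmoid(t_xy) - 0.5 + grid) * stride`` and
``size = anchor * (2*sigmoid(t_wh))**2``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .anchors import DEFAULT_ANCHORS, STRIDES, AnchorSet
from .boxes import Box, Detection, ValidationError
from .nn import engine as E
from .nn.engine import Var

__all__ = ["ModelConfig", "Detector", "build_model", "count_parameters",
           "decode_predictions", "save_checkpoint", "load_checkpoint"]

_BASE_CHANNELS = (64, 128, 256, 512, 1024)
_BASE_DEPTHS = (3, 6, 9, 3)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the detector."""

    num_classes: int = 1
    depth_multiple: float = 0.33
    width_multiple: float = 0.50
    input_size: int = 640
    anchors: AnchorSet = field(default_factory=lambda: DEFAULT_ANCHORS)
    ca_reduction: int = 32
    ca_sites: tuple[str, ...] = ()          # subset of {"backbone_c3", "neck"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_multiple <= 0 or self.width_multiple <= 0:
            raise ValidationError("depth/width multiples must be positive")
        if self.input_size % 32 != 0:
            raise ValidationError(f"input_size must be divisible by 32, got {self.input_size}")
        if self.ca_reduction < 1:
            raise ValidationError("ca_reduction must be >= 1")
        unknown = set(self.ca_sites) - {"backbone_c3", "neck"}
        if unknown:
            raise ValidationError(f"unknown ca_sites {sorted(unknown)}")

    @classmethod
    def tiny(cls, **kwargs) -> "ModelConfig":
        """CPU-friendly preset: width 0.125, 160 px input, anchors rescaled."""
        defaults = dict(width_multiple=0.125, input_size=160,
                        anchors=DEFAULT_ANCHORS.scaled(0.25))
        defaults.update(kwargs)
        return cls(**defaults)

    def replace(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "num_classes": self.num_classes,
            "depth_multiple": self.depth_multiple,
            "width_multiple": self.width_multiple,
            "input_size": self.input_size,
            "anchors": [list(a) for a in self.anchors.anchors],
            "ca_reduction": self.ca_reduction,
            "ca_sites": list(self.ca_sites),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["anchors"] = AnchorSet(tuple(tuple(a) for a in d["anchors"]))
        d["ca_sites"] = tuple(d["ca_sites"])
        return cls(**d)


def _width(c: int, multiple: float) -> int:
    return max(8, int(math.ceil(c * multiple / 8) * 8))


def _depth(n: int, multiple: float) -> int:
    return max(1, round(n * multiple))


class Detector(nn.Module):
    """The assembled network; call with an (N, 3, S, S) array in [0, 1]."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = lambda c: _width(c, config.width_multiple)
        d = lambda n: _depth(n, config.depth_multiple)
        c64, c128, c256, c512, c1024 = (w(c) for c in _BASE_CHANNELS)
        n3, n6, n9, n3b = (d(n) for n in _BASE_DEPTHS)
        backbone_c3 = "backbone_c3" in config.ca_sites
        red = config.ca_reduction

        def c3(c1, c2, n, shortcut=True):
            if backbone_c3:
                return nn.C3CA(c1, c2, n, shortcut, reduction=red, rng=rng)
            return nn.C3(c1, c2, n, shortcut, rng=rng)

        # backbone
        self.stem = nn.Focus(3, c64, 3, rng=rng)
        self.b1 = nn.ConvBNSiLU(c64, c128, 3, 2, rng=rng)
        self.b2 = c3(c128, c128, n3)
        self.b3 = nn.ConvBNSiLU(c128, c256, 3, 2, rng=rng)
        self.b4 = c3(c256, c256, n6)
        self.b5 = nn.ConvBNSiLU(c256, c512, 3, 2, rng=rng)
        self.b6 = c3(c512, c512, n9)
        self.b7 = nn.ConvBNSiLU(c512, c1024, 3, 2, rng=rng)
        self.b8 = c3(c1024, c1024, n3b)
        self.sppf = nn.SPPF(c1024, c1024, 5, rng=rng)

        # neck (FPN top-down, then PAN bottom-up); fusion C3s without shortcut
        self.n_lat5 = nn.ConvBNSiLU(c1024, c512, 1, rng=rng)
        self.n_fuse4 = nn.C3(c1024, c512, n3b, False, rng=rng)
        self.n_lat4 = nn.ConvBNSiLU(c512, c256, 1, rng=rng)
        self.n_fuse3 = nn.C3(c512, c256, n3b, False, rng=rng)
        self.n_down3 = nn.ConvBNSiLU(c256, c256, 3, 2, rng=rng)
        self.n_fuse4b = nn.C3(c512, c512, n3b, False, rng=rng)
        self.n_down4 = nn.ConvBNSiLU(c512, c512, 3, 2, rng=rng)
        self.n_fuse5b = nn.C3(c1024, c1024, n3b, False, rng=rng)
        if "neck" in config.ca_sites:
            self.ca4 = nn.CoordAtt(c512, red, rng=rng)
            self.ca3 = nn.CoordAtt(c256, red, rng=rng)
            self.ca4b = nn.CoordAtt(c512, red, rng=rng)
            self.ca5b = nn.CoordAtt(c1024, red, rng=rng)

        # heads
        no = 3 * (5 + config.num_classes)
        self.head3 = nn.PlainConv(c256, no, 1, rng=rng)
        self.head4 = nn.PlainConv(c512, no, 1, rng=rng)
        self.head5 = nn.PlainConv(c1024, no, 1, rng=rng)
        self._init_head_biases()

    def _init_head_biases(self) -> None:
        """Prior-probability bias init: rare objectness, uniform classes."""
        nc = self.config.num_classes
        for head, stride in zip((self.head3, self.head4, self.head5), STRIDES):
            b = head.bias.data.reshape(3, 5 + nc)
            b[:, 4] = math.log(8.0 / (self.config.input_size / stride) ** 2)
            b[:, 5:] = math.log(0.6 / max(nc - 0.99, 0.01)) if nc > 1 else 0.0
            head.bias.data = b.reshape(-1)

    def __call__(self, x: np.ndarray | Var) -> list[Var]:
        """Forward pass; returns raw per-scale grids (N, 3*(5+nc), K, K)."""
        if not isinstance(x, Var):
            x = Var(np.asarray(x, dtype=np.float64))
        if x.data.ndim != 4 or x.data.shape[1] != 3:
            raise ValidationError(f"expected (N, 3, H, W) input, got {x.shape}")
        if x.data.shape[2] % 32 or x.data.shape[3] % 32:
            raise ValidationError("input spatial size must be divisible by 32")
        neck_ca = "neck" in self.config.ca_sites

        y = self.stem(x)
        y = self.b2(self.b1(y))
        p3 = self.b4(self.b3(y))
        p4 = self.b6(self.b5(p3))
        p5 = self.sppf(self.b8(self.b7(p4)))

        lat5 = self.n_lat5(p5)
        f4 = self.n_fuse4(E.concat([E.upsample2(lat5), p4], axis=1))
        if neck_ca:
            f4 = self.ca4(f4)
        lat4 = self.n_lat4(f4)
        f3 = self.n_fuse3(E.concat([E.upsample2(lat4), p3], axis=1))
        if neck_ca:
            f3 = self.ca3(f3)
        f4b = self.n_fuse4b(E.concat([self.n_down3(f3), lat4], axis=1))
        if neck_ca:
            f4b = self.ca4b(f4b)
        f5b = self.n_fuse5b(E.concat([self.n_down4(f4b), lat5], axis=1))
        if neck_ca:
            f5b = self.ca5b(f5b)

        return [self.head3(f3), self.head4(f4b), self.head5(f5b)]

    # -- accounting --------------------------------------------------------

    def fused_num_parameters(self) -> int:
        """Parameter count of the deployed network with conv+BN fused.

        Each conv+BN pair collapses to a conv with bias: the two BN affine
        vectors are replaced by one bias vector, removing one scalar per
        normalized channel relative to the raw trainable count.
        """
        total = 0
        stack: list[nn.Module] = [self]
        while stack:
            m = stack.pop()
            if isinstance(m, nn.ConvBNSiLU):
                total += m.fused_num_parameters()
            else:
                if isinstance(m, nn.PlainConv):
                    total += m.weight.data.size + m.bias.data.size
                stack.extend(m._children.values())
        return total


def build_model(config: ModelConfig) -> Detector:
    """Assemble a detector from its configuration."""
    return Detector(config)


def count_parameters(network: nn.Module, fused: bool = False) -> int:
    """Number of model parameters.

    ``fused=False`` counts raw trainable scalars (conv weights plus the two
    batch-norm affine vectors).  ``fused=True`` counts the deployed form in
    which each conv+BN pair is fused into a biased convolution — the
    convention used by common detector summaries at inference time.
    """
    if fused:
        if not isinstance(network, Detector):
            raise ValidationError("fused counting is defined for full Detector models")
        return network.fused_num_parameters()
    return network.num_parameters()


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def decode_scale(raw: np.ndarray, anchors_wh: np.ndarray, stride: int,
                 num_classes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decode one scale's raw grid (N, 3*(5+nc), K, K).

    Returns ``(boxes_cxcywh, obj, cls)`` with shapes (N, 3, K, K, 4),
    (N, 3, K, K) and (N, 3, K, K, nc), in input-image pixels.
    """
    N, C, K, K2 = raw.shape
    no = 5 + num_classes
    if C != 3 * no or K != K2:
        raise ValidationError(f"raw grid shape {raw.shape} inconsistent with "
                              f"{num_classes} classes")
    r = raw.reshape(N, 3, no, K, K).transpose(0, 1, 3, 4, 2)  # (N,3,K,K,no)
    gy, gx = np.mgrid[0:K, 0:K]
    xy = (2 * _sigmoid(r[..., 0:2]) - 0.5
          + np.stack([gx, gy], axis=-1)[None, None]) * stride
    wh = (2 * _sigmoid(r[..., 2:4])) ** 2 * anchors_wh[None, :, None, None, :]
    obj = _sigmoid(r[..., 4])
    cls = _sigmoid(r[..., 5:])
    return np.concatenate([xy, wh], axis=-1), obj, cls


def decode_predictions(raw: list[np.ndarray | Var], anchors: AnchorSet,
                       num_classes: int = 1, input_size: int | None = None,
                       conf_threshold: float = 0.001) -> list[list[Detection]]:
    """Decode raw per-scale grids into per-image pixel-space detections.

    ``score = sigmoid(obj) * max_c sigmoid(cls_c)``; boxes are clipped to the
    image square.  Detections below ``conf_threshold`` are dropped.
    """
    arrays = [r.data if isinstance(r, Var) else np.asarray(r) for r in raw]
    if len(arrays) != 3:
        raise ValidationError("expected raw predictions at 3 scales")
    per_scale_anchors = anchors.per_scale()
    if input_size is None:
        input_size = arrays[0].shape[-1] * STRIDES[0]
    N = arrays[0].shape[0]
    out: list[list[Detection]] = [[] for _ in range(N)]
    for r, aw, stride in zip(arrays, per_scale_anchors, STRIDES):
        if r.shape[-1] * stride != input_size:
            raise ValidationError(
                f"scale grid {r.shape[-1]} inconsistent with stride {stride} "
                f"and input size {input_size}")
        boxes, obj, cls = decode_scale(r, aw, stride, num_classes)
        score = obj[..., None] * cls                        # (N,3,K,K,nc)
        best_cls = score.argmax(axis=-1)
        best_score = score.max(axis=-1)
        for n in range(N):
            keep = np.argwhere(best_score[n] >= conf_threshold)
            for a, gy, gx in keep:
                cx, cy, w, h = boxes[n, a, gy, gx]
                x0 = min(max(cx - w / 2, 0.0), input_size)
                y0 = min(max(cy - h / 2, 0.0), input_size)
                x1 = min(max(cx + w / 2, 0.0), input_size)
                y1 = min(max(cy + h / 2, 0.0), input_size)
                if x1 - x0 <= 0 or y1 - y0 <= 0:
                    continue
                out[n].append(Detection(
                    box=Box.from_corners(x0, y0, x1, y1),
                    score=float(min(best_score[n, a, gy, gx], 1.0)),
                    class_index=int(best_cls[n, a, gy, gx]),
                ))
    return out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: Detector, path: str | Path, extra: dict | None = None) -> None:
    """Serialize weights + config (+ optional metadata) to one .npz file."""
    payload = dict(model.state_dict())
    meta = {"config": model.config.to_dict(), "extra": extra or {}}
    payload["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> tuple[Detector, dict]:
    """Rebuild a detector from a checkpoint; returns (model, metadata)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model = Detector(ModelConfig.from_dict(meta["config"]))
    model.load_state_dict(state)
    return model, meta.get("extra", {})
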
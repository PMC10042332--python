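"""Network building blocks: CBS convs, CSP bottlenecks, C3/C3CA, SPPF, Focus,
coordinate attention.

Parameter registration is by attribute insertion order, which makes state
dicts and optimizer slots deterministic.  Convolutions followed by batch
norm carry no bias; detection-head convolutions do.
"""

from __future__ import annotations

import numpy as np

from . import engine as E
from .engine import Param, Var

__all__ = [
    "Module", "ModuleList", "ConvBNSiLU", "PlainConv", "Bottleneck",
    "C3", "C3CA", "CoordAtt", "SPPF", "Focus",
]


class Module:
    """Tiny module base: child/param discovery via attribute order."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Param):
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Param]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Param]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for cname, child in self._children.items():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = [(prefix + n, b) for n, b in self._buffers.items()]
        for cname, child in self._children.items():
            out.extend(child.named_buffers(prefix + cname + "."))
        return out

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {n: p.data.copy() for n, p in self.named_parameters()}
        d.update({"buffer::" + n: b.copy() for n, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.data = np.asarray(d[n], dtype=np.float64).copy()
        for n, b in self.named_buffers():
            b[...] = d["buffer::" + n]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, m: Module) -> None:
        self._children[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)


def _he_conv(rng: np.random.Generator, c2: int, c1: int, k: int) -> np.ndarray:
    fan_in = c1 * k * k
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c2, c1, k, k))


class ConvBNSiLU(Module):
    """CBS unit: convolution (no bias) + batch norm + SiLU."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 rng: np.random.Generator | None = None, act: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c1, self.c2, self.k, self.s = c1, c2, k, s
        self.act = act
        self.weight = Param(_he_conv(rng, c2, c1, k))
        self.gamma = Param(np.ones(c2))
        self.beta = Param(np.zeros(c2))
        self.register_buffer("running_mean", np.zeros(c2))
        self.register_buffer("running_var", np.ones(c2))

    def __call__(self, x: Var) -> Var:
        y = E.conv2d(x, self.weight, stride=self.s)
        y = E.batchnorm(y, self.gamma, self.beta, self.running_mean,
                        self.running_var, self.training)
        return E.silu(y) if self.act else y

    def fused_num_parameters(self) -> int:
        # conv weight + the bias that absorbs BN at inference
        return self.weight.data.size + self.c2


class PlainConv(Module):
    """Convolution with bias and no norm (detection heads, CA gate convs)."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.s = s
        self.weight = Param(_he_conv(rng, c2, c1, k))
        self.bias = Param(np.zeros(c2))

    def __call__(self, x: Var) -> Var:
        return E.conv2d(x, self.weight, self.bias, stride=self.s)


class Bottleneck(Module):
    """Residual 1x1 -> 3x3 pair; shortcut only when shapes match."""

    def __init__(self, c1: int, c2: int, shortcut: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cv1 = ConvBNSiLU(c1, c2, 1, rng=rng)
        self.cv2 = ConvBNSiLU(c2, c2, 3, rng=rng)
        self.add = shortcut and c1 == c2

    def __call__(self, x: Var) -> Var:
        y = self.cv2(self.cv1(x))
        return E.add(x, y) if self.add else y


class C3(Module):
    """CSP bottleneck stack with three CBS convs (the YOLOv5 C3 block)."""

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        c_ = c2 // 2
        self.c_ = c_
        self.cv1 = ConvBNSiLU(c1, c_, 1, rng=rng)
        self.cv2 = ConvBNSiLU(c1, c_, 1, rng=rng)
        self.cv3 = ConvBNSiLU(2 * c_, c2, 1, rng=rng)
        self.m = ModuleList([Bottleneck(c_, c_, shortcut, rng=rng) for _ in range(n)])

    def __call__(self, x: Var) -> Var:
        a = self.cv1(x)
        for b in self.m:
            a = b(a)
        return self.cv3(E.concat([a, self.cv2(x)], axis=1))


class CoordAtt(Module):
    """Coordinate attention: directional pooling -> shared 1x1 -> two gates.

    Features are average-pooled along width (giving a C x H x 1 column) and
    along height (C x 1 x W row); the two are concatenated and passed through
    a shared 1x1 conv + BN + SiLU down to ``max(8, C // reduction)``
    channels, split back, and mapped by two per-direction 1x1 convs to
    sigmoid gates that multiplicatively rescale the input.
    """

    def __init__(self, c: int, reduction: int = 32,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if reduction < 1:
            raise ValueError("reduction must be >= 1")
        mid = max(8, c // reduction)
        self.conv1 = ConvBNSiLU(c, mid, 1, rng=rng)
        self.conv_h = PlainConv(mid, c, 1, rng=rng)
        self.conv_w = PlainConv(mid, c, 1, rng=rng)

    def __call__(self, x: Var) -> Var:
        if x.data.ndim != 4:
            raise ValueError(f"coordinate attention expects NCHW input, got shape {x.shape}")
        H, W = x.data.shape[2], x.data.shape[3]
        ph = E.mean_axis(x, axis=3)                      # (N, C, H, 1)
        pw = E.transpose_hw(E.mean_axis(x, axis=2))      # (N, C, W, 1)
        y = self.conv1(E.concat([ph, pw], axis=2))       # (N, mid, H+W, 1)
        yh = E.narrow(y, 0, H, axis=2)
        yw = E.transpose_hw(E.narrow(y, H, W, axis=2))   # (N, mid, 1, W)
        gh = E.sigmoid(self.conv_h(yh))                  # (N, C, H, 1)
        gw = E.sigmoid(self.conv_w(yw))                  # (N, C, 1, W)
        return E.mul(E.mul(x, gh), gw)


class C3CA(Module):
    """C3 with coordinate attention on the bottleneck branch and the CBS on
    the secondary branch removed (replaced by a plain channel-split path).

    Parameter count is strictly below the matching :class:`C3` at standard
    widths: the removed 1x1 conv (c1*c_ weights + BN) outweighs the small CA
    unit.
    """

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = True,
                 reduction: int = 32, rng: np.random.Generator | None = None):
        super().__init__()
        c_ = c2 // 2
        if c1 < c_:
            raise ValueError(f"C3CA needs c1 >= c2 // 2 (got c1={c1}, c2={c2})")
        self.c_ = c_
        self.cv1 = ConvBNSiLU(c1, c_, 1, rng=rng)
        self.cv3 = ConvBNSiLU(2 * c_, c2, 1, rng=rng)
        self.m = ModuleList([Bottleneck(c_, c_, shortcut, rng=rng) for _ in range(n)])
        self.ca = CoordAtt(c_, reduction, rng=rng)

    def __call__(self, x: Var) -> Var:
        a = self.cv1(x)
        for b in self.m:
            a = b(a)
        a = self.ca(a)
        identity = E.narrow(x, 0, self.c_, axis=1)
        return self.cv3(E.concat([a, identity], axis=1))


class SPPF(Module):
    """Serial max-pool pyramid: three cumulative k=5 poolings, concatenated."""

    def __init__(self, c1: int, c2: int, k: int = 5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        c_ = c1 // 2
        self.k = k
        self.cv1 = ConvBNSiLU(c1, c_, 1, rng=rng)
        self.cv2 = ConvBNSiLU(c_ * 4, c2, 1, rng=rng)

    def __call__(self, x: Var) -> Var:
        y = self.cv1(x)
        p1 = E.maxpool2d(y, self.k)
        p2 = E.maxpool2d(p1, self.k)
        p3 = E.maxpool2d(p2, self.k)
        return self.cv2(E.concat([y, p1, p2, p3], axis=1))


class Focus(Module):
    """Slice-and-stack stem: 2x2 pixel de-interleave to 4*C channels + CBS."""

    def __init__(self, c1: int, c2: int, k: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = ConvBNSiLU(4 * c1, c2, k, rng=rng)

    def __call__(self, x: Var) -> Var:
        parts = [E.space_slice(x, 0, 0), E.space_slice(x, 1, 0),
                 E.space_slice(x, 0, 1), E.space_slice(x, 1, 1)]
        return self.conv(E.concat(parts, axis=1))
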
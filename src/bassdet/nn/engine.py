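"""Minimal reverse-mode array autodiff for the detector.

A :class:`Var` wraps a float64 numpy array (NCHW layout for feature maps)
and records the op that produced it; :func:`backward` replays the tape in
reverse topological order.  Only the ops the detection network needs are
implemented: im2col convolution, batch norm, SiLU/sigmoid, elementwise
add/mul with broadcasting, channel concat/slice, strided spatial slicing
(for the Focus stem), max pooling, nearest 2x upsampling, directional mean
pooling and H/W transposition (for coordinate attention).

Parameters are :class:`Param` leaves: persistent Vars whose ``grad``
accumulates across calls until explicitly zeroed by the optimizer.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Var", "Param", "backward"]


class Var:
    """Node in the computation tape."""

    __slots__ = ("data", "grad", "parents", "backward_fn")

    def __init__(self, data: np.ndarray,
                 parents: tuple["Var", ...] = (),
                 backward_fn: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self.backward_fn = backward_fn

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g


class Param(Var):
    """Trainable leaf; ``grad`` persists until zeroed."""

    __slots__ = ("name",)

    def __init__(self, data: np.ndarray, name: str = ""):
        super().__init__(data)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad = np.zeros_like(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        assert self.grad is not None
        self.grad += g


def backward(seeds: Sequence[tuple[Var, np.ndarray]]) -> None:
    """Backpropagate ``d(out)`` gradients from the seed nodes to all leaves."""
    topo: list[Var] = []
    seen: set[int] = set()
    stack: list[tuple[Var, bool]] = [(v, False) for v, _ in seeds]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    for v, g in seeds:
        v.accumulate(np.asarray(g, dtype=np.float64))
    for node in reversed(topo):
        if node.grad is None or node.backward_fn is None:
            continue
        node.backward_fn(node.grad)
        if not isinstance(node, Param):
            node.grad = None  # free intermediate grads as we go


# ---------------------------------------------------------------------------
# elementwise & shape ops
# ---------------------------------------------------------------------------

def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Var, b: Var) -> Var:
    out = Var(a.data + b.data, (a, b))

    def bw(g):
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(_unbroadcast(g, b.data.shape))
    out.backward_fn = bw
    return out


def mul(a: Var, b: Var) -> Var:
    out = Var(a.data * b.data, (a, b))

    def bw(g):
        a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        b.accumulate(_unbroadcast(g * a.data, b.data.shape))
    out.backward_fn = bw
    return out


def sigmoid(x: Var) -> Var:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))
    out = Var(s, (x,))

    def bw(g):
        x.accumulate(g * s * (1.0 - s))
    out.backward_fn = bw
    return out


def silu(x: Var) -> Var:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))
    out = Var(x.data * s, (x,))

    def bw(g):
        x.accumulate(g * s * (1.0 + x.data * (1.0 - s)))
    out.backward_fn = bw
    return out


def concat(parts: Sequence[Var], axis: int = 1) -> Var:
    out = Var(np.concatenate([p.data for p in parts], axis=axis), tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for p, o, n in zip(parts, offsets, sizes):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(o, o + n)
            p.accumulate(g[tuple(idx)])
    out.backward_fn = bw
    return out


def narrow(x: Var, start: int, length: int, axis: int = 1) -> Var:
    """Contiguous slice along an axis (channel split)."""
    idx = [slice(None)] * x.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    out = Var(x.data[idx], (x,))

    def bw(g):
        full = np.zeros_like(x.data)
        full[idx] = g
        x.accumulate(full)
    out.backward_fn = bw
    return out


def space_slice(x: Var, row0: int, col0: int, step: int = 2) -> Var:
    """Strided spatial subsampling x[..., row0::step, col0::step] (Focus stem)."""
    out = Var(x.data[:, :, row0::step, col0::step], (x,))

    def bw(g):
        full = np.zeros_like(x.data)
        full[:, :, row0::step, col0::step] = g
        x.accumulate(full)
    out.backward_fn = bw
    return out


def mean_axis(x: Var, axis: int) -> Var:
    """Mean along one axis, keepdims (directional average pooling)."""
    n = x.data.shape[axis]
    out = Var(x.data.mean(axis=axis, keepdims=True), (x,))

    def bw(g):
        x.accumulate(np.broadcast_to(g / n, x.data.shape).copy())
    out.backward_fn = bw
    return out


def transpose_hw(x: Var) -> Var:
    """Swap the two spatial axes of an NCHW tensor."""
    out = Var(x.data.transpose(0, 1, 3, 2), (x,))

    def bw(g):
        x.accumulate(g.transpose(0, 1, 3, 2))
    out.backward_fn = bw
    return out


def upsample2(x: Var) -> Var:
    """Nearest-neighbor 2x spatial upsampling."""
    out = Var(x.data.repeat(2, axis=2).repeat(2, axis=3), (x,))

    def bw(g):
        N, C, H2, W2 = g.shape
        x.accumulate(g.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))
    out.backward_fn = bw
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    N, C, H, W = x.shape
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    cols = np.empty((N, C, k, k, Ho, Wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride]
    return cols.reshape(N, C * k * k, Ho * Wo), (Ho, Wo)


def _col2im(dcols: np.ndarray, xshape, k: int, stride: int, pad: int,
            out_hw: tuple[int, int]) -> np.ndarray:
    N, C, H, W = xshape
    Ho, Wo = out_hw
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(N, C, k, k, Ho, Wo)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Var, weight: Var, bias: Var | None = None,
           stride: int = 1, pad: int | None = None) -> Var:
    """2-D convolution, NCHW; ``pad`` defaults to 'same' for odd kernels."""
    Cout, Cin, k, _ = weight.data.shape
    if pad is None:
        pad = k // 2
    cols, (Ho, Wo) = _im2col(x.data, k, stride, pad)
    wmat = weight.data.reshape(Cout, Cin * k * k)
    y = np.matmul(wmat, cols)                      # (N, Cout, L)
    if bias is not None:
        y = y + bias.data[None, :, None]
    N = x.data.shape[0]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Var(y.reshape(N, Cout, Ho, Wo), parents)

    def bw(g):
        gmat = g.reshape(N, Cout, Ho * Wo)
        weight.accumulate(np.einsum("ncl,nkl->ck", gmat, cols,
                                    optimize=True).reshape(weight.data.shape))
        if bias is not None:
            bias.accumulate(gmat.sum(axis=(0, 2)))
        dcols = np.matmul(wmat.T, gmat)            # (N, Cin*k*k, L)
        x.accumulate(_col2im(dcols, x.data.shape, k, stride, pad, (Ho, Wo)))
    out.backward_fn = bw
    return out


def maxpool2d(x: Var, k: int, stride: int = 1, pad: int | None = None) -> Var:
    """Max pooling; default padding keeps the spatial size at stride 1."""
    if pad is None:
        pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                constant_values=-np.inf)
    N, C, H, W = xp.shape
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    stack = np.empty((k * k, N, C, Ho, Wo), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            stack[i * k + j] = xp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride]
    arg = stack.argmax(axis=0)
    y = np.take_along_axis(stack, arg[None], axis=0)[0]
    out = Var(y, (x,))

    def bw(g):
        dxp = np.zeros((N, C, H, W), dtype=g.dtype)
        for idx in range(k * k):
            mask = arg == idx
            if not mask.any():
                continue
            i, j = divmod(idx, k)
            dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += g * mask
        if pad:
            dxp = dxp[:, :, pad:-pad, pad:-pad]
        x.accumulate(dxp)
    out.backward_fn = bw
    return out


def batchnorm(x: Var, gamma: Var, beta: Var, running_mean: np.ndarray,
              running_var: np.ndarray, training: bool,
              momentum: float = 0.03, eps: float = 1e-5) -> Var:
    """Per-channel batch normalization over (N, H, W).

    In training mode batch statistics are used and the running estimates are
    updated in place; in eval mode the running estimates are used.
    """
    axes = (0, 2, 3)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = x.data.size / x.data.shape[1]
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var * m / max(m - 1, 1)
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = Var(y, (x, gamma, beta))

    def bw(g):
        gamma.accumulate((g * xhat).sum(axis=axes))
        beta.accumulate(g.sum(axis=axes))
        gi = gamma.data[None, :, None, None] * inv[None, :, None, None]
        if training:
            m = x.data.size / x.data.shape[1]
            gmean = g.mean(axis=axes)[None, :, None, None]
            gxhat = (g * xhat).mean(axis=axes)[None, :, None, None]
            x.accumulate(gi * (g - gmean - xhat * gxhat))
        else:
            x.accumulate(gi * g)
    out.backward_fn = bw
    return out
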
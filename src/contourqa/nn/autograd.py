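"""Reverse-mode autodiff over float32 NumPy arrays.

Feature tensors are laid out channels-first: (batch, channels, x, y, z).
Every op builds the output Tensor with a closure that accumulates gradients
into its parents; ``backward()`` topologically sorts the graph and runs the
closures in reverse.  Only the ops the quality network needs are provided.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor with seed 1."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data: np.ndarray):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def silu(x: Tensor) -> Tensor:
    s = _stable_sigmoid(x.data)
    out_data = x.data * s

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * s * (1.0 + x.data * (1.0 - s)))

    return Tensor(out_data, parents=(x,), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = _stable_sigmoid(x.data)

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=bwd)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Value clamp with pass-through gradient inside the interval."""
    out_data = np.clip(x.data, lo, hi)
    inside = (x.data > lo) & (x.data < hi)

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * inside)

    return Tensor(out_data, parents=(x,), backward=bwd)


def prelu(x: Tensor, alpha: Tensor) -> Tensor:
    """PReLU with one learnable slope per channel (axis 1)."""
    a = alpha.data.reshape(1, -1, *([1] * (x.data.ndim - 2)))
    neg = x.data < 0
    out_data = np.where(neg, a * x.data, x.data)

    def bwd(g):
        if x.requires_grad:
            x.accumulate(np.where(neg, a, 1.0) * g)
        if alpha.requires_grad:
            ga = np.where(neg, x.data, 0.0) * g
            axes = (0,) + tuple(range(2, x.data.ndim))
            alpha.accumulate(ga.sum(axis=axes))

    return Tensor(out_data, parents=(x, alpha), backward=bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, X, Y, Z) -> (B, C) spatial mean."""
    axes = tuple(range(2, x.data.ndim))
    n = float(np.prod([x.data.shape[i] for i in axes]))
    out_data = x.data.mean(axis=axes)

    def bwd(g):
        if x.requires_grad:
            x.accumulate(
                np.broadcast_to(g.reshape(g.shape + (1,) * len(axes)), x.data.shape) / n
            )

    return Tensor(out_data, parents=(x,), backward=bwd)


def nearest_resize(x: Tensor, out_spatial: tuple[int, int, int]) -> Tensor:
    """Nearest-neighbor resampling of the spatial axes of (B, C, X, Y, Z)."""
    in_spatial = x.data.shape[2:]
    idx = [
        (np.arange(o) * i) // o  # floor mapping, exact for integer factors
        for o, i in zip(out_spatial, in_spatial)
    ]
    out_data = x.data[:, :, idx[0]][:, :, :, idx[1]][:, :, :, :, idx[2]]

    def bwd(g):
        if not x.requires_grad:
            return
        gin = g
        for ax, (o, i, ix) in enumerate(zip(out_spatial, in_spatial, idx)):
            axis = ax + 2
            moved = np.moveaxis(gin, axis, 0)
            acc = np.zeros((i,) + moved.shape[1:], dtype=np.float32)
            np.add.at(acc, ix, moved)
            gin = np.moveaxis(acc, 0, axis)
        x.accumulate(gin)

    return Tensor(out_data, parents=(x,), backward=bwd)


def fast_normalized_fusion(
    inputs: Sequence[Tensor], weights: Tensor, epsilon: float = 1e-4
) -> Tensor:
    """Weighted feature fusion Σ wᵢ·Iᵢ / (ε + Σ wᵢ) with wᵢ = max(0, raw wᵢ).

    ``weights`` holds one raw learnable scalar per input; rectification
    keeps the combination a convex-like average and training stable.
    """
    if len(inputs) != weights.data.shape[0]:
        raise ValueError("need exactly one weight per input")
    shape = inputs[0].data.shape
    for t in inputs[1:]:
        if t.data.shape != shape:
            raise ValueError(f"fusion input shapes differ: {t.data.shape} vs {shape}")
    w = np.maximum(weights.data, 0.0)
    denom = epsilon + w.sum()
    out_data = sum(wi * t.data for wi, t in zip(w, inputs)) / denom

    def bwd(g):
        for wi, t in zip(w, inputs):
            if t.requires_grad:
                t.accumulate(g * (wi / denom))
        if weights.requires_grad:
            gw = np.array(
                [
                    float((g * (t.data - out_data)).sum()) / denom if raw > 0 else 0.0
                    for raw, t in zip(weights.data, inputs)
                ],
                dtype=np.float32,
            )
            weights.accumulate(gw)

    return Tensor(out_data, parents=tuple(inputs) + (weights,), backward=bwd)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target array."""
    t = np.asarray(target, dtype=np.float32).reshape(pred.data.shape)
    diff = pred.data - t
    out_data = np.array((diff**2).mean(), dtype=np.float32)

    def bwd(g):
        if pred.requires_grad:
            pred.accumulate(g * 2.0 * diff / diff.size)

    return Tensor(out_data, parents=(pred,), backward=bwd)


# ---------------------------------------------------------------------------
# convolutions (channels-first, padding 1 for 3x3x3 kernels)
# ---------------------------------------------------------------------------

_OFFSETS = [(i, j, k) for i in range(3) for j in range(3) for k in range(3)]


def conv1x1(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """Pointwise convolution: w is (Cout, Cin)."""
    out_data = np.einsum("oc,bcxyz->boxyz", w.data, x.data, optimize=True)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1, 1)

    def bwd(g):
        if x.requires_grad:
            x.accumulate(np.einsum("oc,boxyz->bcxyz", w.data, g, optimize=True))
        if w.requires_grad:
            w.accumulate(np.einsum("boxyz,bcxyz->oc", g, x.data, optimize=True))
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3, 4)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=bwd)


def _pad_spatial(a: np.ndarray) -> np.ndarray:
    return np.pad(a, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))


def _out_size(n: int, s: int) -> int:
    return (n - 1) // s + 1  # padded 3-kernel: ceil(n / s)


def conv3x3(x: Tensor, w: Tensor, b: Optional[Tensor], stride: tuple[int, int, int]) -> Tensor:
    """Full 3x3x3 convolution, padding 1; w is (Cout, Cin, 3, 3, 3).

    Implemented as a sum over the 27 kernel offsets of strided slices — no
    im2col buffer, cheap for the small channel counts it is used with.
    """
    xp = _pad_spatial(x.data)
    B, C = x.data.shape[:2]
    sx, sy, sz = stride
    ox, oy, oz = (_out_size(n, s) for n, s in zip(x.data.shape[2:], stride))
    Cout = w.data.shape[0]
    out_data = np.zeros((B, Cout, ox, oy, oz), dtype=np.float32)
    for i, j, k in _OFFSETS:
        sl = xp[:, :, i:i + sx * ox:sx, j:j + sy * oy:sy, k:k + sz * oz:sz]
        out_data += np.einsum("oc,bcxyz->boxyz", w.data[:, :, i, j, k], sl, optimize=True)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1, 1)

    def bwd(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i, j, k in _OFFSETS:
                gxp[:, :, i:i + sx * ox:sx, j:j + sy * oy:sy, k:k + sz * oz:sz] += \
                    np.einsum("oc,boxyz->bcxyz", w.data[:, :, i, j, k], g, optimize=True)
            x.accumulate(gxp[:, :, 1:-1, 1:-1, 1:-1])
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for i, j, k in _OFFSETS:
                sl = xp[:, :, i:i + sx * ox:sx, j:j + sy * oy:sy, k:k + sz * oz:sz]
                gw[:, :, i, j, k] = np.einsum("boxyz,bcxyz->oc", g, sl, optimize=True)
            w.accumulate(gw)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3, 4)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=bwd)


def dwconv3x3(x: Tensor, w: Tensor, b: Optional[Tensor], stride: tuple[int, int, int]) -> Tensor:
    """Depthwise 3x3x3 convolution, padding 1; w is (C, 3, 3, 3)."""
    xp = _pad_spatial(x.data)
    sx, sy, sz = stride
    ox, oy, oz = (_out_size(n, s) for n, s in zip(x.data.shape[2:], stride))
    B, C = x.data.shape[:2]
    out_data = np.zeros((B, C, ox, oy, oz), dtype=np.float32)
    for i, j, k in _OFFSETS:
        out_data += w.data[None, :, i, j, k, None, None, None] * \
            xp[:, :, i:i + sx * ox:sx, j:j + sy * oy:sy, k:k + sz * oz:sz]
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1, 1)

    def bwd(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i, j, k in _OFFSETS:
                gxp[:, :, i:i + sx * ox:sx, j:j + sy * oy:sy, k:k + sz * oz:sz] += \
                    w.data[None, :, i, j, k, None, None, None] * g
            x.accumulate(gxp[:, :, 1:-1, 1:-1, 1:-1])
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for i, j, k in _OFFSETS:
                sl = xp[:, :, i:i + sx * ox:sx, j:j + sy * oy:sy, k:k + sz * oz:sz]
                gw[:, i, j, k] = (g * sl).sum(axis=(0, 2, 3, 4))
            w.accumulate(gw)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3, 4)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=bwd)


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (batch, spatial) per channel.

    In training mode, batch statistics are used and the running buffers are
    updated in place; in eval mode the running buffers are used.
    """
    axes = (0,) + tuple(range(2, x.data.ndim))
    bshape = (1, -1) + (1,) * (x.data.ndim - 2)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        n = float(np.prod([x.data.shape[i] for i in axes]))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var * (n / max(n - 1.0, 1.0))
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(bshape)) * invstd.reshape(bshape)
    out_data = gamma.data.reshape(bshape) * xhat + beta.data.reshape(bshape)

    def bwd(g):
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=axes))
        if x.requires_grad:
            gz = g * gamma.data.reshape(bshape)
            if training:
                n = float(np.prod([x.data.shape[i] for i in axes]))
                gm = gz.mean(axis=axes).reshape(bshape)
                gxh = (gz * xhat).mean(axis=axes).reshape(bshape)
                gx = (gz - gm - xhat * gxh) * invstd.reshape(bshape)
            else:
                gx = gz * invstd.reshape(bshape)
            x.accumulate(gx)

    return Tensor(out_data, parents=(x, gamma, beta), backward=bwd)
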
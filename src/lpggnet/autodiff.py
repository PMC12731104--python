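"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough tensor machinery for the model in this package: broadcasting
elementwise arithmetic, (batched) matmul, reductions, valid 1-D convolution,
max/average pooling, GeLU/ReLU, clamping, concatenation and a fused
softmax cross-entropy.  Everything runs in float64, which keeps
finite-difference gradient checks tight.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "maxpool1d", "avgpool_to",
           "softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad over broadcast dimensions so it matches ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- elementwise arithmetic -------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        a, b = self, Tensor._coerce(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))
        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)
        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._coerce(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))
        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        b = Tensor._coerce(other)
        return self * b ** -1.0

    def __rtruediv__(self, other):
        return Tensor._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)
        out_data = a.data ** e

        def backward(g):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1.0))
        return Tensor._make(out_data, (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data)
        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g / a.data)
        return Tensor._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- activations -------------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)
        return Tensor._make(a.data * mask, (a,), backward)

    def gelu(self):
        """Exact GeLU: 0.5 x (1 + erf(x / sqrt(2)))."""
        from scipy.special import erf
        a = self
        x = a.data
        phi = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))

        def backward(g):
            if a.requires_grad:
                pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
                a._accum(g * (phi + x * pdf))
        return Tensor._make(x * phi, (a,), backward)

    def clamp(self, lo: float | None = None, hi: float | None = None):
        a = self
        out_data = np.clip(a.data, lo, hi)
        mask = np.ones_like(a.data)
        if lo is not None:
            mask *= a.data >= lo
        if hi is not None:
            mask *= a.data <= hi

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)
        return Tensor._make(out_data, (a,), backward)

    # -- linear algebra ----------------------------------------------------
    def __matmul__(self, other):
        a, b = self, Tensor._coerce(other)

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))
        return Tensor._make(a.data @ b.data, (a, b), backward)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(np.swapaxes(g, ax1, ax2))
        return Tensor._make(np.swapaxes(a.data, ax1, ax2), (a,), backward)

    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(old))
        return Tensor._make(a.data.reshape(*shape), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)
        return Tensor._make(a.data[idx], (a,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.full_like(a.data, float(g)))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())
        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims),
                            (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors, axis: int = 0) -> Tensor:
    ts = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis),
                        ts, backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Valid 1-D convolution (cross-correlation) along the last axis.

    x: (B, C_in, L); w: (C_out, C_in, k); b: (C_out,).
    Returns (B, C_out, L - k + 1).
    """
    k = w.data.shape[-1]
    if x.data.shape[-1] < k:
        raise ValueError(
            f"input length {x.data.shape[-1]} shorter than kernel {k}")
    windows = np.lib.stride_tricks.sliding_window_view(x.data, k, axis=2)
    out_data = np.einsum("bilk,oik->bol", windows, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if w.requires_grad:
            gw = np.einsum("bol,bilk->oik", g, windows, optimize=True)
            w._accum(gw)
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            l_out = g.shape[-1]
            for j in range(k):
                gx[:, :, j:j + l_out] += np.einsum(
                    "bol,oi->bil", g, w.data[:, :, j], optimize=True)
            x._accum(gx)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
    return Tensor._make(out_data, parents, backward)


def maxpool1d(x: Tensor, width: int) -> Tensor:
    """Non-overlapping max pooling along the last axis (trailing remainder
    samples are dropped)."""
    b_shape = x.data.shape[:-1]
    l = x.data.shape[-1]
    l_out = l // width
    trimmed = x.data[..., :l_out * width].reshape(*b_shape, l_out, width)
    arg = trimmed.argmax(axis=-1)
    out_data = np.take_along_axis(trimmed, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros((*b_shape, l_out, width))
        np.put_along_axis(gx, arg[..., None], g[..., None], axis=-1)
        full = np.zeros_like(x.data)
        full[..., :l_out * width] = gx.reshape(*b_shape, l_out * width)
        x._accum(full)
    return Tensor._make(out_data, (x,), backward)


def avgpool_to(x: Tensor, frames: int) -> Tensor:
    """Average-pool the last axis down to ``frames`` equal segments
    (trailing remainder samples are dropped)."""
    l = x.data.shape[-1]
    if l < frames:
        raise ValueError(f"cannot pool length {l} to {frames} frames")
    width = l // frames
    b_shape = x.data.shape[:-1]
    trimmed = x.data[..., :frames * width].reshape(*b_shape, frames, width)
    out_data = trimmed.mean(axis=-1)

    def backward(g):
        if not x.requires_grad:
            return
        full = np.zeros_like(x.data)
        spread = np.repeat(g[..., None], width, axis=-1) / width
        full[..., :frames * width] = spread.reshape(*b_shape, frames * width)
        x._accum(full)
    return Tensor._make(out_data, (x,), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over the batch, softmax folded in via
    log-sum-exp.  logits: (B, C); labels: (B,) integer class ids."""
    z = logits.data
    labels = np.asarray(labels, dtype=int)
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    n = z.shape[0]
    loss = float((lse - z[np.arange(n), labels]).mean())
    probs = np.exp(z - lse[:, None])

    def backward(g):
        if logits.requires_grad:
            grad = probs.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accum(float(g) * grad / n)
    return Tensor._make(loss, (logits,), backward)
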
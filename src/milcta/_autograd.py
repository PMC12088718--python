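"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the vectorized operations the MIL network needs (dense and
3×3 convolution layers, pooling, pointwise nonlinearities, reductions and
batched matmul) with gradients verified by finite differences in the test
suite.  Tensors keep the dtype they are constructed with, so float64 is used
for gradient checks and float32 for training throughput.
"""

from __future__ import annotations

import numpy as np


def _as_float(data):
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over broadcast dimensions back to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_float(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            if node._backward is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, n: float):
        a = self

        def bwd(g):
            a._accum(g * n * a.data ** (n - 1.0))

        return Tensor._make(a.data**n, (a,), bwd)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bwd)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            a._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (a,), bwd)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

        def bwd(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bwd)

    def exp(self):
        a = self
        out_data = np.exp(np.clip(a.data, -60, 60))

        def bwd(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def bwd(g):
            a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(*shape), (a,), bwd)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            a._accum(g.transpose(*inv))

        return Tensor._make(a.data.transpose(*axes), (a,), bwd)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        shape = a.data.shape

        def bwd(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            denom = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            denom = int(np.prod([self.data.shape[i] for i in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    # -- linear algebra ------------------------------------------------------
    def matmul(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g @ b.data.swapaxes(-1, -2), a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(a.data.swapaxes(-1, -2) @ g, b.data.shape))

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    __matmul__ = matmul


def conv2d_3x3(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """Same-padded 3×3 convolution: x (B,Ci,H,W), w (Co,Ci,3,3), b (Co,).

    Computed as nine shifted tensor contractions (one per kernel tap), which
    keeps memory traffic low; ``stride`` subsamples the output grid.
    """
    B, Ci, H, W = x.data.shape
    Co = w.data.shape[0]
    Ho, Wo = -(-H // stride), -(-W // stride)
    xpad = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    y = np.zeros((B, Ho, Wo, Co), dtype=x.data.dtype)
    for di in range(3):
        for dj in range(3):
            patch = xpad[:, :, di : di + H : stride, dj : dj + W : stride]
            y += np.tensordot(patch, w.data[:, :, di, dj], axes=([1], [1]))
    out_data = y.transpose(0, 3, 1, 2) + b.data[None, :, None, None]

    def bwd(g):
        gp = g.transpose(0, 2, 3, 1)  # (B,Ho,Wo,Co)
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for di in range(3):
                for dj in range(3):
                    patch = xpad[:, :, di : di + H : stride, dj : dj + W : stride]
                    gw[:, :, di, dj] = np.tensordot(gp, patch, axes=([0, 1, 2], [0, 2, 3]))
            w._accum(gw)
        if x.requires_grad:
            gxpad = np.zeros_like(xpad)
            for di in range(3):
                for dj in range(3):
                    gxpad[:, :, di : di + H : stride, dj : dj + W : stride] += np.tensordot(
                        gp, w.data[:, :, di, dj], axes=([3], [0])
                    ).transpose(0, 3, 1, 2)
            x._accum(gxpad[:, :, 1 : H + 1, 1 : W + 1])

    return Tensor._make(out_data, (x, w, b), bwd)


def maxpool2x2(x: Tensor) -> Tensor:
    """2×2 max pooling with stride 2; an odd trailing row/column is dropped.

    Ties within a window route the gradient to a single winner.
    """
    B, C, H, W = x.data.shape
    if H < 2 or W < 2:
        raise ValueError("maxpool2x2 requires spatial dimensions of at least 2")
    He, We = (H // 2) * 2, (W // 2) * 2
    xc = x.data[:, :, :He, :We]
    r = xc.reshape(B, C, He // 2, 2, We // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, He // 2, We // 2, 4)
    idx = r.argmax(axis=-1)
    out_data = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gr = np.zeros_like(r)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, :, :He, :We] = (
            gr.reshape(B, C, He // 2, We // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, He, We)
        )
        x._accum(gx)

    return Tensor._make(out_data, (x,), bwd)


def global_max(x: Tensor) -> Tensor:
    """Maximum over the last axis; ties route the gradient to one winner."""
    idx = x.data.argmax(axis=-1)
    out_data = np.take_along_axis(x.data, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx[..., None], g[..., None], axis=-1)
        x._accum(gx)

    return Tensor._make(out_data, (x,), bwd)


def concat_last(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two tensors along the last axis."""
    na = a.data.shape[-1]

    def bwd(g):
        if a.requires_grad:
            a._accum(g[..., :na])
        if b.requires_grad:
            b._accum(g[..., na:])

    return Tensor._make(np.concatenate([a.data, b.data], axis=-1), (a, b), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (the max shift carries no gradient)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + eps) ** -0.5 * gamma + beta
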
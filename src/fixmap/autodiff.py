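"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the few-shot reconstruction classifier
needs: broadcast arithmetic, matmul, transpose/reshape/slicing, reductions,
elementwise nonlinearities, matrix inverse, and a strided 2-D convolution.
Gradients are accumulated by a topological sweep over the recorded tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "sgd_step"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req,
                      _parents=parents if req else (),
                      _backward=backward if req else None)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if not self.requires_grad and not self._parents:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic --------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(g)
            other._accum(g)

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data ** 2)

        return self._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return self._make(self.data @ other.data, (self, other), bwd)

    def square(self):
        return self * self

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accum(g * 0.5 / np.maximum(out_data, 1e-300))

        return self._make(out_data, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bwd)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bwd)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(self.data[idx], (self,), bwd)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- linear algebra ----------------------------------------------------

    def inv(self):
        """Matrix inverse of a square 2-D tensor."""
        out_data = np.linalg.inv(self.data)

        def bwd(g):
            self._accum(-out_data.T @ g @ out_data.T)

        return self._make(out_data, (self,), bwd)


def concat(tensors, axis=0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    return Tensor(data, requires_grad=req,
                  _parents=tuple(tensors) if req else (),
                  _backward=bwd if req else None)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    b, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    cols = np.empty((b, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return cols.reshape(b, c * kh * kw, oh * ow), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int):
    b, c, h, w = x_shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    cols = cols.reshape(b, c, kh, kw, oh, ow)
    x = np.zeros(x_shape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols[:, :, i, j]
    return x


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution: x (B,C,H,W), w (F,C,kh,kw), b (F,). Returns (B,F,oh,ow)."""
    x = Tensor._lift(x)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="constant") if pad else x.data
    f, c, kh, kw = w.data.shape
    cols, oh, ow = _im2col(xp, kh, kw, stride)           # (B, C*kh*kw, oh*ow)
    wf = w.data.reshape(f, -1)
    out_data = np.einsum("fk,bkp->bfp", wf, cols).reshape(-1, f, oh, ow)
    out_data += b.data.reshape(1, f, 1, 1)

    def bwd(g):
        gf = g.reshape(g.shape[0], f, -1)                # (B, F, oh*ow)
        b._accum(gf.sum(axis=(0, 2)))
        w._accum(np.einsum("bfp,bkp->fk", gf, cols).reshape(w.data.shape))
        dcols = np.einsum("fk,bfp->bkp", wf, gf)
        dxp = _col2im(dcols, xp.shape, kh, kw, stride)
        if pad:
            dxp = dxp[:, :, pad:-pad, pad:-pad]
        x._accum(dxp)

    req = x.requires_grad or w.requires_grad or b.requires_grad
    return Tensor(out_data, requires_grad=req,
                  _parents=(x, w, b) if req else (),
                  _backward=bwd if req else None)


def sgd_step(params, lr: float) -> None:
    """Plain stochastic gradient descent update in place."""
    for p in params:
        if p.grad is not None:
            p.data -= lr * p.grad
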
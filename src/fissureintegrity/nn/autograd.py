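"""Tape-based reverse-mode autodiff on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operation that produced
it; calling :meth:`Tensor.backward` on a scalar output walks the tape in
reverse topological order accumulating gradients into every tensor created
with ``requires_grad=True``.  Only the operations needed by a 3D attention
U-Net are provided: broadcast arithmetic, ReLU/sigmoid, channel softmax,
3D convolution (im2col), 2x max-pooling, 2x nearest upsampling, channel
concatenation, instance normalization, and axis sums.

Gradient correctness is established by numerical finite-difference checks
in the test suite rather than by construction.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: working precision; float64 is useful for finite-difference verification
DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward):
        t = cls(data)
        if any(p.requires_grad or p._parents for p in parents):
            t._parents = tuple(parents)
            t._backward = backward
            t.requires_grad = True
        return t

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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free closures/caches

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=self.data.dtype),
                            self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out_parents = (self, other)

        def bwd(g):
            self._accum(g)
            other._accum(g)
        return Tensor._from_op(self.data + other.data, out_parents, bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)
        return Tensor._from_op(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)
        return Tensor._from_op(-self.data, (self,), bwd)

    def __sub__(self, other):
        other = self._wrap(other)

        def bwd(g):
            self._accum(g)
            other._accum(-g)
        return Tensor._from_op(self.data - other.data, (self, other), bwd)

    def __rsub__(self, other):
        return self._wrap(other) - self

    def __truediv__(self, other):
        other = self._wrap(other)

        def bwd(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data ** 2))
        return Tensor._from_op(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def sum(self, axes=None, keepdims: bool = False):
        data = self.data.sum(axis=axes, keepdims=keepdims)
        shape = self.data.shape

        def bwd(g):
            if axes is not None and not keepdims:
                ax = (axes,) if isinstance(axes, int) else axes
                g = np.expand_dims(g, tuple(sorted(ax)))
            self._accum(np.broadcast_to(g, shape))
        return Tensor._from_op(data, (self,), bwd)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# -- nonlinearities --------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        x._accum(g * mask)
    return Tensor._from_op(x.data * mask, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        x._accum(g * s * (1.0 - s))
    return Tensor._from_op(s, (x,), bwd)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 of an (N, C, ...) tensor."""
    m = x.data.max(axis=1, keepdims=True)
    e = np.exp(x.data - m)
    p = e / e.sum(axis=1, keepdims=True)

    def bwd(g):
        dot = (g * p).sum(axis=1, keepdims=True)
        x._accum(p * (g - dot))
    return Tensor._from_op(p, (x,), bwd)


# -- structural ops --------------------------------------------------------

def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    na = a.data.shape[1]

    def bwd(g):
        a._accum(g[:, :na])
        b._accum(g[:, na:])
    return Tensor._from_op(np.concatenate([a.data, b.data], axis=1),
                           (a, b), bwd)


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling; spatial dims must be even."""
    n, c, X, Y, Z = x.data.shape
    if X % 2 or Y % 2 or Z % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(X, Y, Z)}")
    v = (x.data.reshape(n, c, X // 2, 2, Y // 2, 2, Z // 2, 2)
         .transpose(0, 1, 2, 4, 6, 3, 5, 7)
         .reshape(n, c, X // 2, Y // 2, Z // 2, 8))
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        dv = np.zeros_like(v)
        np.put_along_axis(dv, idx[..., None], g[..., None], axis=-1)
        dx = (dv.reshape(n, c, X // 2, Y // 2, Z // 2, 2, 2, 2)
              .transpose(0, 1, 2, 5, 3, 6, 4, 7)
              .reshape(n, c, X, Y, Z))
        x._accum(dx)
    return Tensor._from_op(out, (x,), bwd)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x upsampling of the three spatial axes."""
    n, c, X, Y, Z = x.data.shape
    out = (x.data.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4))

    def bwd(g):
        dx = (g.reshape(n, c, X, 2, Y, 2, Z, 2).sum(axis=(3, 5, 7)))
        x._accum(dx)
    return Tensor._from_op(out, (x,), bwd)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: int | None = None) -> Tensor:
    """3D convolution, stride 1.  ``x``: (N, Cin, X, Y, Z); ``w``:
    (Cout, Cin, k, k, k); default 'same' padding k//2."""
    co, ci, k, _, _ = w.data.shape
    pad = k // 2 if padding is None else padding
    n = x.data.shape[0]
    if pad:
        xp = np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    else:
        xp = x.data
    spatial = tuple(s + 2 * pad - k + 1 for s in x.data.shape[2:])
    V = int(np.prod(spatial))
    if k == 1:
        cols = xp.reshape(n, ci, V)
    else:
        v = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        cols = (v.transpose(0, 1, 5, 6, 7, 2, 3, 4)
                .reshape(n, ci * k ** 3, V))
    w2 = w.data.reshape(co, ci * k ** 3)
    out = np.matmul(w2, cols).reshape(n, co, *spatial)
    if b is not None:
        out = out + b.data.reshape(1, co, 1, 1, 1)

    def bwd(g):
        g2 = g.reshape(n, co, V)
        if w.requires_grad or w._parents:
            dw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dw.reshape(w.data.shape))
        if b is not None:
            b._accum(g2.sum(axis=(0, 2)))
        if not (x.requires_grad or x._parents):
            return
        dcols = np.matmul(w2.T, g2)           # (n, ci*k^3, V)
        if k == 1:
            dxp = dcols.reshape(n, ci, *spatial)
            x._accum(dxp if pad == 0 else
                     dxp[:, :, pad:-pad, pad:-pad, pad:-pad])
        else:
            dxp = np.zeros_like(xp)
            d6 = dcols.reshape(n, ci, k, k, k, *spatial)
            sx, sy, sz = spatial
            for i, j, l in product(range(k), repeat=3):
                dxp[:, :, i:i + sx, j:j + sy, l:l + sz] += d6[:, :, i, j, l]
            if pad:
                dxp = dxp[:, :, pad:-pad, pad:-pad, pad:-pad]
            x._accum(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._from_op(out, parents, bwd)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes with a
    learnable affine (``gamma``, ``beta`` of shape (C,))."""
    n, c = x.data.shape[:2]
    ax = (2, 3, 4)
    M = int(np.prod(x.data.shape[2:]))
    mean = x.data.mean(axis=ax, keepdims=True)
    var = x.data.var(axis=ax, keepdims=True)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * invstd
    gam = gamma.data.reshape(1, c, 1, 1, 1)
    out = gam * xhat + beta.data.reshape(1, c, 1, 1, 1)

    def bwd(g):
        gamma._accum((g * xhat).sum(axis=(0, 2, 3, 4)))
        beta._accum(g.sum(axis=(0, 2, 3, 4)))
        dxhat = g * gam
        # standard normalization backward over the spatial axes
        dx = (dxhat - dxhat.mean(axis=ax, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=ax, keepdims=True)) * invstd
        x._accum(dx)
        del dx
    _ = M
    return Tensor._from_op(out, (x, gamma, beta), bwd)
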
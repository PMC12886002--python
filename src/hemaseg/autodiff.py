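"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the tensor operations the segmentation network needs:
broadcast arithmetic, matmul, ReLU, exp/log/power, reductions, reshaping,
concatenation, softmax, strided 2-D convolution and 2x bilinear upsampling.
Gradients are accumulated by topological traversal of the recorded graph.
All data is float64; determinism follows from numpy's.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables graph recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer mixed ndarray <op> Tensor expressions to the
    # reflected Tensor operators instead of broadcasting elementwise
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- graph construction --------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = grad.copy() if isinstance(grad, np.ndarray) else np.asarray(grad)
        else:
            self.grad = self.grad + grad

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()
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

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _coerce(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        a, b = self, Tensor._coerce(other)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._coerce(other)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._coerce(other)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        a = self

        def bwd(g):
            a._accumulate(g * p * a.data ** (p - 1))

        return Tensor._make(a.data ** p, (a,), bwd)

    def __matmul__(self, other):
        a, b = self, Tensor._coerce(other)

        def bwd(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    def __getitem__(self, key):
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            a._accumulate(full)

        return Tensor._make(a.data[key], (a,), bwd)

    # -- elementwise nonlinearities --------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            a._accumulate(g * mask)

        return Tensor._make(a.data * mask, (a,), bwd)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    def sqrt(self):
        return self ** 0.5

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed only where unclipped."""
        a = self
        mask = (a.data >= lo) & (a.data <= hi)

        def bwd(g):
            a._accumulate(g * mask)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), bwd)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
                return
            if not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, ax)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._make(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation ----------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            a._accumulate(g.reshape(a.data.shape))

        return Tensor._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            a._accumulate(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    a = t
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        a._accumulate(s * (g - dot))

    return Tensor._make(s, (a,), bwd)


# -- spatial primitives (NCHW) ------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(B,C,H,W) -> windows (B,C,Ho,Wo,k,k) view on the padded array."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), x:(B,C,H,W), w:(Cout,Cin,k,k)."""
    k = w.data.shape[-1]
    Bn, Cin, H, W = x.data.shape
    win = _im2col(x.data, k, stride, padding)  # (B,Cin,Ho,Wo,k,k)
    Ho, Wo = win.shape[2], win.shape[3]
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(Bn, Ho, Wo, Cin * k * k)
    wmat = w.data.reshape(w.data.shape[0], Cin * k * k)
    out = col @ wmat.T + b.data  # (B,Ho,Wo,Cout)
    out = out.transpose(0, 3, 1, 2)

    def bwd(g):
        gcol = g.transpose(0, 2, 3, 1)  # (B,Ho,Wo,Cout)
        if b.requires_grad:
            b._accumulate(gcol.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            gw = np.tensordot(gcol, col, axes=([0, 1, 2], [0, 1, 2]))  # (Cout, Cin*k*k)
            w._accumulate(gw.reshape(w.data.shape))
        if x.requires_grad:
            dcol = gcol @ wmat  # (B,Ho,Wo,Cin*k*k)
            dwin = dcol.reshape(Bn, Ho, Wo, Cin, k, k).transpose(0, 3, 1, 2, 4, 5)
            xp = np.zeros((Bn, Cin, H + 2 * padding, W + 2 * padding))
            for i in range(k):
                for j in range(k):
                    xp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += dwin[:, :, :, :, i, j]
            x._accumulate(xp[:, :, padding:padding + H, padding:padding + W])

    return Tensor._make(out, (x, w, b), bwd)


def _bilinear_indices(n_in: int):
    """Half-pixel-aligned source indices/weights for a 2x upsample."""
    src = (np.arange(2 * n_in) + 0.5) / 2.0 - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    w1 = np.clip(src - i0, 0.0, 1.0)
    return i0, i1, 1.0 - w1, w1


def upsample2x(x: Tensor) -> Tensor:
    """Bilinear 2x spatial upsampling of (B,C,H,W), half-pixel alignment."""
    Bn, C, H, W = x.data.shape
    iy0, iy1, wy0, wy1 = _bilinear_indices(H)
    ix0, ix1, wx0, wx1 = _bilinear_indices(W)
    ry0, ry1 = iy0[:, None], iy1[:, None]
    cx0, cx1 = ix0[None, :], ix1[None, :]
    W00 = wy0[:, None] * wx0[None, :]
    W01 = wy0[:, None] * wx1[None, :]
    W10 = wy1[:, None] * wx0[None, :]
    W11 = wy1[:, None] * wx1[None, :]
    d = x.data
    out = (W00 * d[:, :, ry0, cx0] + W01 * d[:, :, ry0, cx1]
           + W10 * d[:, :, ry1, cx0] + W11 * d[:, :, ry1, cx1])

    def bwd(g):
        dx = np.zeros_like(x.data)
        np.add.at(dx, (slice(None), slice(None), ry0, cx0), g * W00)
        np.add.at(dx, (slice(None), slice(None), ry0, cx1), g * W01)
        np.add.at(dx, (slice(None), slice(None), ry1, cx0), g * W10)
        np.add.at(dx, (slice(None), slice(None), ry1, cx1), g * W11)
        x._accumulate(dx)

    return Tensor._make(out, (x,), bwd)
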
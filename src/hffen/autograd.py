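"""Compact reverse-mode automatic differentiation on numpy arrays.

This is the numerical substrate for the network: a :class:`Tensor` wrapping an
ndarray, a small set of differentiable operations (matmul, valid 2-D
convolution via im2col, padding, softmax, layer normalisation, elementwise
nonlinearities, reductions, reshapes), and a topological-order backward pass.
Only what the architecture needs is implemented; convolutions are stride-1,
which is all a shape-preserving restoration network requires.

Gradient correctness for every op is pinned against central finite
differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    # -- graph plumbing -------------------------------------------------------

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar output")
            grad = np.ones_like(self.data)
        # topological order via iterative DFS
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("tensor/tensor division is not needed")
        return self * (1.0 / other)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other
        out = a.data @ b.data

        def bw(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(out, (a, b), bw)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def bw(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def bw(g):
            if a.requires_grad:
                a._accum(np.transpose(g, inv))

        return Tensor._make(np.transpose(a.data, axes), (a,), bw)

    def crop2d(self, top: int, left: int, height: int, width: int) -> "Tensor":
        """Spatial crop of a (..., H, W) tensor; backward zero-embeds."""
        a = self

        def bw(g):
            if a.requires_grad:
                gx = np.zeros_like(a.data)
                gx[..., top : top + height, left : left + width] = g
                a._accum(gx)

        return Tensor._make(
            a.data[..., top : top + height, left : left + width].copy(), (a,), bw
        )

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if not a.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            if a.grad is not None:
                a.grad += gg  # broadcasting add, no materialisation
            else:
                out = np.empty_like(a.data)
                np.copyto(out, gg)
                a.grad = out

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def bw(g):
            if a.requires_grad:
                a._accum(g * sign)

        return Tensor._make(np.abs(a.data), (a,), bw)

    # -- nonlinearities -------------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bw)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return Tensor._make(s, (a,), bw)

    def gelu(self):
        """Exact Gaussian-error-linear unit: x * Phi(x)."""
        a = self
        x = a.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))

        def bw(g):
            if a.requires_grad:
                pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
                a._accum(g * (phi + x * pdf))

        return Tensor._make(x * phi, (a,), bw)

    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            if a.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                a._accum(s * (g - dot))

        return Tensor._make(s, (a,), bw)

    # -- padding and convolution ---------------------------------------------

    def pad2d(self, pad, mode: str = "reflect") -> "Tensor":
        """Pad the last two axes ('reflect' or 'zero').

        `pad` is an int (same on all four sides) or a 4-tuple
        (top, bottom, left, right).
        """
        if isinstance(pad, int):
            pt = pb = pl = pr = pad
        else:
            pt, pb, pl, pr = pad
        if pt == pb == pl == pr == 0:
            return self
        a = self
        H, W = a.data.shape[-2], a.data.shape[-1]
        spec = [(0, 0)] * (a.data.ndim - 2) + [(pt, pb), (pl, pr)]
        if mode == "zero":
            out = np.pad(a.data, spec, mode="constant")

            def bw(g):
                if a.requires_grad:
                    a._accum(g[..., pt : pt + H, pl : pl + W])

        elif mode == "reflect":
            out = np.pad(a.data, spec, mode="reflect")

            def bw(g):
                if not a.requires_grad:
                    return
                if pt == pb == pl == pr == 1:
                    # single copy + 4 edge strips + 4 corners
                    gx = np.ascontiguousarray(g[..., 1 : 1 + H, 1 : 1 + W])
                    gx[..., 1, :] += g[..., 0, 1 : 1 + W]
                    gx[..., H - 2, :] += g[..., H + 1, 1 : 1 + W]
                    gx[..., :, 1] += g[..., 1 : 1 + H, 0]
                    gx[..., :, W - 2] += g[..., 1 : 1 + H, W + 1]
                    gx[..., 1, 1] += g[..., 0, 0]
                    gx[..., 1, W - 2] += g[..., 0, W + 1]
                    gx[..., H - 2, 1] += g[..., H + 1, 0]
                    gx[..., H - 2, W - 2] += g[..., H + 1, W + 1]
                    a._accum(gx)
                    return
                # fold the reflected border strips back onto interior rows/cols
                tmp = np.ascontiguousarray(g[..., pt : pt + H, :])
                for j in range(pt):  # padded row j came from source row pt - j
                    tmp[..., pt - j, :] += g[..., j, :]
                for j in range(pb):  # bottom row maps to H - 2 - j
                    tmp[..., H - 2 - j, :] += g[..., pt + H + j, :]
                gx = np.ascontiguousarray(tmp[..., pl : pl + W])
                for j in range(pl):
                    gx[..., pl - j] += tmp[..., j]
                for j in range(pr):
                    gx[..., W - 2 - j] += tmp[..., pl + W + j]
                a._accum(gx)

        else:
            raise ValueError(f"unknown padding mode: {mode!r}")
        return Tensor._make(out, (a,), bw)

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None) -> "Tensor":
        """Valid (no padding) stride-1 cross-correlation.

        self: (B, Cin, H, W); weight: (Cout, Cin, kh, kw); bias: (Cout,).
        """
        from ._fastops import im2col, to_map, to_rows

        x, w = self, weight
        B, Cin, H, W = x.data.shape
        Cout, Cin_w, kh, kw = w.data.shape
        if Cin != Cin_w:
            raise ValueError(f"conv2d channel mismatch: input {Cin}, weight {Cin_w}")
        Ho, Wo = H - kh + 1, W - kw + 1
        if kh == kw == 1:
            # pointwise: one batched GEMM, no patch extraction
            xr = x.data.reshape(B, Cin, H * W)
            wmat = w.data.reshape(Cout, Cin)
            out = np.matmul(wmat, xr).reshape(B, Cout, H, W)
            if bias is not None:
                out += bias.data.reshape(1, Cout, 1, 1)
            parents = (x, w) if bias is None else (x, w, bias)

            def bw1(g):
                gr = g.reshape(B, Cout, H * W)
                if w.requires_grad:
                    gw = np.matmul(gr, xr.transpose(0, 2, 1)).sum(axis=0)
                    w._accum(gw.reshape(w.data.shape))
                if bias is not None and bias.requires_grad:
                    bias._accum(gr.sum(axis=(0, 2)))
                if x.requires_grad:
                    x._accum(np.matmul(wmat.T, gr).reshape(B, Cin, H, W))

            return Tensor._make(out, parents, bw1)

        col = im2col(x.data, kh, kw)
        wmat = w.data.reshape(Cout, Cin * kh * kw)
        out = to_map(col @ wmat.T, B, Ho, Wo)
        if bias is not None:
            out += bias.data.reshape(1, Cout, 1, 1)
        parents = (x, w) if bias is None else (x, w, bias)

        def bw(g):
            gmat = to_rows(g)
            if w.requires_grad:
                w._accum((gmat.T @ col).reshape(w.data.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(gmat.sum(axis=0))
            if x.requires_grad:
                # full correlation of g with spatially flipped, axis-swapped kernel
                gp = np.pad(
                    g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1))
                )
                gcol = im2col(gp, kh, kw)
                wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(
                    Cin, Cout * kh * kw
                )
                x._accum(to_map(gcol @ wflip.T, B, H, W))

        return Tensor._make(out, parents, bw)

    def depthwise_conv2d(self, kernel: np.ndarray) -> "Tensor":
        """Valid stride-1 cross-correlation with one fixed (kh, kw) kernel
        applied independently to every channel. The kernel is a plain ndarray
        and receives no gradient."""
        x = self
        k = np.asarray(kernel, dtype=x.data.dtype)
        kh, kw = k.shape
        B, C, H, W = x.data.shape
        win = sliding_window_view(x.data, (kh, kw), axis=(2, 3))
        out = np.einsum("bchwij,ij->bchw", win, k, optimize=True)

        def bw(g):
            if x.requires_grad:
                gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
                gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
                gx = np.einsum("bchwij,ij->bchw", gwin, k[::-1, ::-1], optimize=True)
                x._accum(gx)

        return Tensor._make(out, (x,), bw)

    def layer_norm(
        self, gamma: "Tensor", beta: "Tensor", axis: int = 1, eps: float = 1e-5
    ) -> "Tensor":
        """Normalise over one axis (mean 0, var 1), then scale/shift.

        For a (B, C, H, W) map with axis=1 this is per-position channel
        normalisation; gamma/beta have shape broadcastable to the input
        (e.g. (1, C, 1, 1))."""
        x = self
        mu = x.data.mean(axis=axis, keepdims=True)
        xc = x.data - mu
        var = (xc * xc).mean(axis=axis, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = xhat * gamma.data + beta.data
        n = x.data.shape[axis]

        def bw(g):
            if gamma.requires_grad:
                gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
            if beta.requires_grad:
                beta._accum(_unbroadcast(g, beta.data.shape))
            if x.requires_grad:
                gy = g * gamma.data
                t1 = gy.sum(axis=axis, keepdims=True)
                t2 = (gy * xhat).sum(axis=axis, keepdims=True)
                x._accum(inv * (gy - t1 / n - xhat * t2 / n))

        return Tensor._make(out, (x, gamma, beta), bw)
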
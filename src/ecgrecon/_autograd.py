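"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` runs reverse accumulation over the recorded tape.
Only the primitives needed by the reconstruction networks are provided:
broadcasting arithmetic, (batched) matmul, reshaping/transposition, indexing
and row scatter, reductions, elementwise nonlinearities, zero padding, and
1-D/2-D "same" convolutions implemented via im2col.

Index selections that drive the sparse-attention machinery (top-u queries,
sampled keys, dominant frequencies) are plain integer arrays computed from
``Tensor.data`` — they are treated as constants of the forward pass, so no
gradient flows through the selection itself, only through the selected
values.
"""

from __future__ import annotations

import contextlib
import math

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "stack", "concat", "default_dtype", "get_default_dtype"]

_DEFAULT_DTYPE = np.float64


def get_default_dtype():
    return _DEFAULT_DTYPE


@contextlib.contextmanager
def default_dtype(dtype):
    """Temporarily set the dtype new tensors are created with.

    Training runs use float32 for speed and memory; the oracle-equivalence
    and gradient tests keep the float64 default.
    """
    global _DEFAULT_DTYPE
    prev = _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype)
    try:
        yield
    finally:
        _DEFAULT_DTYPE = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_children", "_backward",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, _children=(), _backward=None):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._grad_owned = False
        self._children = tuple(_children)
        self._backward = _backward

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        # First accumulation keeps a reference (no copy); gradient arrays
        # are never mutated by producers after being passed here, and the
        # topological schedule finalizes a node's grad before its backward
        # runs.  A second accumulation materializes an owned array.
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS post-order (graphs can be thousands of nodes deep)
        visiting: list[tuple[Tensor, bool]] = [(self, False)]
        stack_ = visiting
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for child in node._children:
                if id(child) not in seen:
                    stack_.append((child, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers ------------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, children, backward) -> "Tensor":
        req = any(c.requires_grad for c in children)
        return Tensor(data, requires_grad=req, _children=children if req else (),
                      _backward=backward if req else None)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def bw(g):
            self._maybe(g, lambda gg: self._accum(_unbroadcast(gg, self.data.shape)))
            other._maybe(g, lambda gg: other._accum(_unbroadcast(gg, other.data.shape)))

        return self._make(out_data, (self, other), bw)

    def _maybe(self, g, fn):
        if self.requires_grad:
            fn(g)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)
        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def bw(g):
            self._maybe(g, lambda gg: self._accum(_unbroadcast(gg * other.data, self.data.shape)))
            other._maybe(g, lambda gg: other._accum(_unbroadcast(gg * self.data, other.data.shape)))

        return self._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def bw(g):
            self._maybe(g, lambda gg: self._accum(_unbroadcast(gg / other.data, self.data.shape)))
            other._maybe(g, lambda gg: other._accum(
                _unbroadcast(-gg * self.data / other.data ** 2, other.data.shape)))

        return self._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return self._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), bw)

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            self._accum(g.reshape(old))

        return self._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return self._make(out_data, (self,), bw)

    def swapaxes(self, a, b):
        out_data = np.swapaxes(self.data, a, b)

        def bw(g):
            self._accum(np.swapaxes(g, a, b))

        return self._make(out_data, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            self._accum(buf)

        return self._make(out_data, (self,), bw)

    def index_fill_rows(self, idx, values: "Tensor") -> "Tensor":
        """Copy of self with ``self[idx] = values`` (no duplicate indices)."""
        values = self._wrap(values)
        out_data = np.array(self.data, copy=True)
        out_data[idx] = values.data

        def bw(g):
            if self.requires_grad:
                gb = np.array(g, copy=True)
                gb[idx] = 0.0
                self._accum(gb)
            if values.requires_grad:
                values._accum(_unbroadcast(g[idx], values.data.shape))

        return self._make(out_data, (self, values), bw)

    def pad_axis(self, axis: int, before: int, after: int) -> "Tensor":
        widths = [(0, 0)] * self.data.ndim
        widths[axis] = (before, after)
        out_data = np.pad(self.data, widths)
        sl = [slice(None)] * self.data.ndim
        sl[axis] = slice(before, before + self.data.shape[axis])
        sl = tuple(sl)

        def bw(g):
            self._accum(g[sl])

        return self._make(out_data, (self,), bw)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, shape).copy())

        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = math.prod(self.data.shape[a] for a in axes)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise --------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            self._accum(g / self.data)

        return self._make(out_data, (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bw)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        phi = 0.5 * (1.0 + _erf(x / math.sqrt(2.0)))
        out_data = x * phi

        def bw(g):
            pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
            self._accum(g * (phi + x * pdf))

        return self._make(out_data, (self,), bw)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along ``axis`` (in-place internals)."""
        out_data = self.data - self.data.max(axis=axis, keepdims=True)
        np.exp(out_data, out=out_data)
        out_data /= out_data.sum(axis=axis, keepdims=True)

        def bw(g):
            gg = g * out_data
            dot = gg.sum(axis=axis, keepdims=True)
            gg -= dot * out_data
            self._accum(gg)

        return self._make(out_data, (self,), bw)

    # -- convolutions -------------------------------------------------------

    def conv1d(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """"Same"-padded 1-D convolution.

        self: (B, L, Cin); weight: (K, Cin, Cout) with K odd; bias: (Cout,).
        Returns (B, L, Cout).
        """
        weight = self._wrap(weight)
        bias = self._wrap(bias)
        B, L, cin = self.data.shape
        K, cin_w, cout = weight.data.shape
        if cin_w != cin:
            raise ValueError(f"conv1d channel mismatch: input {cin}, kernel {cin_w}")
        if K % 2 != 1:
            raise ValueError("conv1d requires an odd kernel width")
        p = K // 2
        xp = np.pad(self.data, ((0, 0), (p, p), (0, 0)))
        # (B, L, K, Cin)
        cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)
        cols = cols.transpose(0, 1, 3, 2).reshape(B, L, K * cin)
        wflat = weight.data.reshape(K * cin, cout)
        out_data = cols @ wflat + bias.data

        def bw(g):
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 1)))
            if weight.requires_grad:
                gw = cols.reshape(-1, K * cin).T @ g.reshape(-1, cout)
                weight._accum(gw.reshape(K, cin, cout))
            if self.requires_grad:
                dcols = (g @ wflat.T).reshape(B, L, K, cin)
                dxp = np.zeros_like(xp)
                for k in range(K):
                    dxp[:, k:k + L, :] += dcols[:, :, k, :]
                self._accum(dxp[:, p:p + L, :])

        return self._make(out_data, (self, weight, bias), bw)

    def conv2d(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """"Same"-padded 2-D convolution.

        self: (B, H, W, Cin); weight: (kh, kw, Cin, Cout), kh/kw odd;
        bias: (Cout,).  Returns (B, H, W, Cout).
        """
        weight = self._wrap(weight)
        bias = self._wrap(bias)
        B, H, W, cin = self.data.shape
        kh, kw, cin_w, cout = weight.data.shape
        if cin_w != cin:
            raise ValueError(f"conv2d channel mismatch: input {cin}, kernel {cin_w}")
        if kh % 2 != 1 or kw % 2 != 1:
            raise ValueError("conv2d requires odd kernel sizes")
        ph, pw = kh // 2, kw // 2
        xp = np.pad(self.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
        # -> (B, H, W, Cin, kh, kw) -> (B, H, W, kh, kw, Cin)
        cols = cols.transpose(0, 1, 2, 4, 5, 3).reshape(B, H, W, kh * kw * cin)
        wflat = weight.data.reshape(kh * kw * cin, cout)
        out_data = cols @ wflat + bias.data

        def bw(g):
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 1, 2)))
            if weight.requires_grad:
                gw = cols.reshape(-1, kh * kw * cin).T @ g.reshape(-1, cout)
                weight._accum(gw.reshape(kh, kw, cin, cout))
            if self.requires_grad:
                dcols = (g @ wflat.T).reshape(B, H, W, kh, kw, cin)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, i:i + H, j:j + W, :] += dcols[:, :, :, i, j, :]
                self._accum(dxp[:, ph:ph + H, pw:pw + W, :])

        return self._make(out_data, (self, weight, bias), bw)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        pieces = np.moveaxis(g, axis, 0)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(out_data, tuple(tensors), bw)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bw)
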
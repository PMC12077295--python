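"""A compact reverse-mode automatic differentiation core.

Supports exactly the operations the detection network and its training loss
need: broadcast arithmetic, elementwise nonlinearities, reductions, advanced
indexing, channel concatenation, same-padding 3D convolution (im2col +
BLAS matmul), 2x max pooling and nearest-neighbor upsampling.  Arrays keep
whatever float dtype they are given, so the network can run in float32 while
numerical tests run in float64.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape), dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) node."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = _node(self.data**exponent, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = bw
        return out

    def __getitem__(self, key):
        out = _node(self.data[key], (self,))

        def bw(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                np.add.at(gx, key, g)
                self._accumulate(gx)

        out._backward = bw
        return out

    # -- reductions & elementwise -----------------------------------------
    def sum(self, axis=None):
        out = _node(self.data.sum(axis=axis), (self,))

        def bw(g):
            if self.requires_grad:
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                else:
                    self._accumulate(
                        np.broadcast_to(np.expand_dims(g, axis), self.data.shape).copy()
                    )

        out._backward = bw
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def exp(self):
        val = np.exp(self.data)
        out = _node(val, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * val)

        out._backward = bw
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def sqrt(self):
        return self**0.5

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the interior."""
        out = _node(np.clip(self.data, lo, hi), (self,))
        mask = (self.data > lo) & (self.data < hi)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(val, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * val * (1 - val))

        out._backward = bw
        return out

    def leaky_relu(self, alpha: float = 0.1):
        out = _node(np.where(self.data > 0, self.data, alpha * self.data), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * np.where(self.data > 0, 1.0, alpha))

        out._backward = bw
        return out


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    out.requires_grad = any(p.requires_grad for p in out._parents)
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Spatial ops on (C, D, H, W) tensors


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding stride-1 3D convolution (cross-correlation).

    ``x``: (C_in, D, H, W); ``w``: (C_out, C_in, k, k, k) with odd k;
    ``b``: (C_out,).  Implemented as shift-and-accumulate: one small GEMM
    per kernel tap, which avoids materializing an im2col matrix.
    """
    c_in, d, h, wd = x.data.shape
    c_out, c_in2, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    assert c_in == c_in2 and k % 2 == 1
    p = k // 2
    n = d * h * wd
    xpad = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)))
    taps = [(di, dj, dk) for di in range(k) for dj in range(k) for dk in range(k)]
    # im2col in (taps*C_in, N) layout: each row block is a contiguous shifted
    # copy of the padded volume, so the copies are cache-friendly and the
    # whole convolution is a single GEMM
    cols = np.empty((len(taps) * c_in, n), dtype=x.data.dtype)
    cols_view = cols.reshape(len(taps), c_in, d, h, wd)
    for t, (di, dj, dk) in enumerate(taps):
        cols_view[t] = xpad[:, di : di + d, dj : dj + h, dk : dk + wd]
    # weight layout matching cols: (C_out, taps*C_in)
    wmat = np.ascontiguousarray(w.data.transpose(0, 2, 3, 4, 1)).reshape(
        c_out, len(taps) * c_in
    )
    y = (wmat @ cols).reshape(c_out, d, h, wd) + b.data[:, None, None, None]
    out = _node(y, (x, w, b))

    def bw(g):
        g2 = np.ascontiguousarray(g).reshape(c_out, n)
        if b.requires_grad:
            b._accumulate(g2.sum(axis=1))
        if w.requires_grad:
            gw = (g2 @ cols.T).reshape(c_out, k, k, k, c_in).transpose(0, 4, 1, 2, 3)
            w._accumulate(np.ascontiguousarray(gw))
        if x.requires_grad:
            gcols = wmat.T @ g2  # (taps*C_in, N)
            gxpad = np.zeros_like(xpad)
            for t, (di, dj, dk) in enumerate(taps):
                gxpad[:, di : di + d, dj : dj + h, dk : dk + wd] += gcols[
                    t * c_in : (t + 1) * c_in
                ].reshape(c_in, d, h, wd)
            x._accumulate(gxpad[:, p : p + d, p : p + h, p : p + wd])

    out._backward = bw
    return out


def maxpool3d(x: Tensor) -> Tensor:
    """2x max pooling on (C, D, H, W); extents must be even."""
    c, d, h, w = x.data.shape
    assert d % 2 == 0 and h % 2 == 0 and w % 2 == 0
    blocks = x.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
    flat = blocks.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
    arg = flat.argmax(axis=-1)
    val = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    out = _node(val, (x,))

    def bw(g):
        if x.requires_grad:
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
            gx = (
                gflat.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
                .transpose(0, 1, 4, 2, 5, 3, 6)
                .reshape(c, d, h, w)
            )
            x._accumulate(gx)

    out._backward = bw
    return out


def upsample3d(x: Tensor) -> Tensor:
    """2x nearest-neighbor upsampling on (C, D, H, W)."""
    val = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)
    out = _node(val, (x,))
    c, d, h, w = x.data.shape

    def bw(g):
        if x.requires_grad:
            gx = g.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6))
            x._accumulate(gx)

    out._backward = bw
    return out


def pad_high(x: Tensor, pads: tuple[int, int, int]) -> Tensor:
    """Zero-pad the high side of the three spatial axes of (C, D, H, W)."""
    pd, ph, pw = pads
    if pd == ph == pw == 0:
        return x
    out = _node(np.pad(x.data, ((0, 0), (0, pd), (0, ph), (0, pw))), (x,))
    c, d, h, w = x.data.shape

    def bw(g):
        if x.requires_grad:
            x._accumulate(g[:, :d, :h, :w])

    out._backward = bw
    return out
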
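"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains encoder-decoder networks and differentiates through the
DRR projection operator; both run on this small, dependency-free engine.
Keeping the engine in-repo makes every forward/backward pass deterministic
bit-for-bit on CPU, which the training and evaluation contracts rely on.

A :class:`Tensor` wraps a float64 ``ndarray`` and records the operations
applied to it; :meth:`Tensor.backward` accumulates gradients by reverse
topological traversal.  Only the operations the reconstruction framework
needs are implemented (elementwise algebra, reductions, matmul, slicing,
concatenation, n-dimensional strided convolution, 2x2 max pooling, and
linear interpolation maps used for resizing/upsampling).
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "conv_nd", "maxpool2d", "axis_linear"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without argument requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (40+ conv layers)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise algebra --------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.shape))
            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.shape))
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))
            out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = _make(self.data ** p, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def abs(self):
        out = _make(np.abs(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def sqrt(self):
        out = _make(np.sqrt(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * 0.5 / np.sqrt(self.data))
        return out

    def relu(self):
        out = _make(np.maximum(self.data, 0.0), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(s, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def _bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self):
        """Global maximum; gradient routes to the first arg-max element."""
        idx = np.unravel_index(int(np.argmax(self.data)), self.shape)
        out = _make(self.data[idx], (self,))
        if out.requires_grad:
            def _bw(g):
                full = np.zeros(self.shape)
                full[idx] = g
                self._accum(full)
            out._backward = _bw
        return out

    def min(self):
        return -((-self).max())

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def moveaxis(self, src, dst):
        out = _make(np.moveaxis(self.data, src, dst), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(np.moveaxis(g, dst, src))
        return out

    def __getitem__(self, key):
        out = _make(self.data[key], (self,))
        if out.requires_grad:
            def _bw(g):
                full = np.zeros(self.shape)
                full[key] = g
                self._accum(full)
            out._backward = _bw
        return out

    def matmul(self, other: "Tensor"):
        other = as_tensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accum(_unbroadcast(ga, self.shape))
                if other.requires_grad:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accum(_unbroadcast(gb, other.shape))
            out._backward = _bw
        return out

    __matmul__ = matmul

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)


def _make(data: np.ndarray, parents: tuple) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, _parents=[p for p in parents if p.requires_grad] if req else ())


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = _bw
    return out


# -- n-dimensional convolution ------------------------------------------------

def _spatial_pad(x: np.ndarray, pad: int, nd: int) -> np.ndarray:
    if pad == 0:
        return x
    width = [(0, 0), (0, 0)] + [(pad, pad)] * nd
    return np.pad(x, width)


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """Strided cross-correlation of ``x`` (N, C, *S) with ``w`` (F, C, *K).

    Works for 2-D and 3-D kernels.  Implemented as a sum over kernel
    offsets of channel-contracting tensordots; the backward pass reuses the
    same offset decomposition (scatter for grad-x, gather for grad-w).
    """
    x, w = as_tensor(x), as_tensor(w)
    nd = w.ndim - 2
    ksz = w.shape[2:]
    xp = _spatial_pad(x.data, padding, nd)
    out_sp = tuple((xp.shape[2 + i] - ksz[i]) // stride + 1 for i in range(nd))
    n, f = x.shape[0], w.shape[0]
    offsets = list(itertools.product(*[range(k) for k in ksz]))

    def _slices(off):
        return tuple(
            slice(off[i], off[i] + out_sp[i] * stride, stride) for i in range(nd)
        )

    y = np.zeros((n, *out_sp, f))
    for off in offsets:
        sl = (slice(None), slice(None)) + _slices(off)
        patch = xp[sl]  # (N, C, *out_sp)
        # contract channel axis: (N, *out, F)
        y += np.tensordot(np.moveaxis(patch, 1, -1), w.data[(slice(None), slice(None)) + off].T, axes=1)
    y = np.moveaxis(y, -1, 1)
    if b is not None:
        y = y + b.data.reshape((1, f) + (1,) * nd)

    parents = [p for p in (x, w, b) if p is not None]
    out = _make(y, tuple(parents))
    if out.requires_grad:
        def _bw(g):
            # g: (N, F, *out_sp)
            g_nlast = np.moveaxis(g, 1, -1)  # (N, *out, F)
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for off in offsets:
                    wk = w.data[(slice(None), slice(None)) + off]  # (F, C)
                    contrib = np.tensordot(g_nlast, wk, axes=1)  # (N, *out, C)
                    sl = (slice(None), slice(None)) + _slices(off)
                    gxp[sl] += np.moveaxis(contrib, -1, 1)
                if padding:
                    core = (slice(None), slice(None)) + tuple(
                        slice(padding, gxp.shape[2 + i] - padding) for i in range(nd)
                    )
                    gxp = gxp[core]
                x._accum(gxp)
            if w.requires_grad:
                gw = np.zeros(w.shape)
                sum_axes = tuple(range(nd + 1))  # N and spatial axes of (N,*out)
                for off in offsets:
                    sl = (slice(None), slice(None)) + _slices(off)
                    patch = np.moveaxis(xp[sl], 1, -1)  # (N, *out, C)
                    gw[(slice(None), slice(None)) + off] = np.tensordot(
                        g_nlast, patch, axes=(sum_axes, sum_axes)
                    )
                w._accum(gw)
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0,) + tuple(range(2, 2 + nd))))
        out._backward = _bw
    return out


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 stride-2 max pooling over the trailing two axes of (N, C, H, W)."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    ho, wo = h // 2, w // 2
    xc = x.data[:, :, : ho * 2, : wo * 2]
    win = xc.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
    idx = win.argmax(axis=-1)
    y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    out = _make(y, (x,))
    if out.requires_grad:
        def _bw(g):
            gw_flat = np.zeros((n, c, ho, wo, 4))
            np.put_along_axis(gw_flat, idx[..., None], g[..., None], axis=-1)
            gx = np.zeros(x.shape)
            gx[:, :, : ho * 2, : wo * 2] = (
                gw_flat.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho * 2, wo * 2)
            )
            x._accum(gx)
        out._backward = _bw
    return out


def interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Linear-interpolation matrix (n_out x n_in), half-pixel-centred sampling.

    Maps a length-``n_in`` signal to ``n_out`` samples; identical numerics for
    upsampling (trilinear x2 in the decoder) and DRR raster resizing, and an
    exact identity when ``n_in == n_out``.
    """
    a = np.zeros((n_out, n_in))
    for i in range(n_out):
        s = (i + 0.5) * n_in / n_out - 0.5
        s = min(max(s, 0.0), n_in - 1.0)
        lo = int(np.floor(s))
        hi = min(lo + 1, n_in - 1)
        t = s - lo
        a[i, lo] += 1.0 - t
        a[i, hi] += t
    return a


def axis_linear(x: Tensor, a: np.ndarray, axis: int) -> Tensor:
    """Apply the linear map ``a`` along one axis of ``x`` (gradient = aᵀ)."""
    x = as_tensor(x)
    y = np.moveaxis(np.tensordot(a, np.moveaxis(x.data, axis, 0), axes=1), 0, axis)
    out = _make(y, (x,))
    if out.requires_grad:
        def _bw(g):
            gx = np.moveaxis(np.tensordot(a.T, np.moveaxis(g, axis, 0), axes=1), 0, axis)
            x._accum(gx)
        out._backward = _bw
    return out
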
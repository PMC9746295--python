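"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is a deliberately small engine providing exactly the operations the
registration and segmentation networks need: elementwise arithmetic,
reductions, 2D convolution (im2col), nearest-neighbour upsampling, channel
concatenation, softmax and a differentiable bilinear warp (spatial
transformer).  Tensors form a DAG; ``Tensor.backward`` runs a topological
sweep accumulating gradients into ``.grad``.

Arrays keep whatever float dtype they are given (networks use float32;
gradient-check tests use float64).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "upsample_nearest2x", "softmax", "warp_bilinear"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helper -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        if not self.requires_grad:
            return
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._wrap(other)

        def bwd(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._wrap(other)

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * Tensor._wrap(other).pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self.pow(-1.0)

    def pow(self, n: float) -> "Tensor":
        out_data = self.data ** n

        def bwd(g):
            self._accum(g * n * self.data ** (n - 1.0))

        return Tensor._make(out_data, (self,), bwd)

    __pow__ = pow

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def log(self) -> "Tensor":
        def bwd(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(np.where(mask, self.data, 0.0), (self,), bwd)

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def bwd(g):
            self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def __getitem__(self, idx) -> "Tensor":
        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), bwd)

    def __matmul__(self, other):
        other = Tensor._wrap(other)

        def bwd(g):
            self._accum(g @ other.data.swapaxes(-1, -2))
            other._accum(self.data.swapaxes(-1, -2) @ g)

        return Tensor._make(self.data @ other.data, (self, other), bwd)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


# -- structural ops ----------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, ho, wo), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    return np.ascontiguousarray(cols), ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 1) -> Tensor:
    """2D convolution (cross-correlation), NCHW layout."""
    n = x.data.shape[0]
    co, ci, kh, kw = w.data.shape
    if x.data.shape[1] != ci:
        raise ValueError(f"conv2d: input has {x.data.shape[1]} channels, kernel expects {ci}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    k = ci * kh * kw
    cols2 = cols.reshape(n, k, ho * wo)
    wm = w.data.reshape(co, k)
    out = (wm @ cols2).reshape(n, co, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, co, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gm = g.reshape(n, co, ho * wo)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        w._accum(np.einsum("nop,nkp->ok", gm, cols2, optimize=True).reshape(w.data.shape))
        if x.requires_grad:
            dcols = (wm.T @ gm).reshape(n, ci, kh, kw, ho, wo)
            hpad, wpad = x.data.shape[2] + 2 * pad, x.data.shape[3] + 2 * pad
            dxp = np.zeros((n, ci, hpad, wpad), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[:, :, i, j]
            if pad:
                dxp = dxp[:, :, pad:-pad, pad:-pad]
            x._accum(dxp)

    return Tensor._make(out, parents, bwd)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bwd(g):
        n, c, h, w = g.shape
        x._accum(g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), bwd)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        gs = g * s
        x._accum(gs - s * gs.sum(axis=axis, keepdims=True))

    return Tensor._make(s, (x,), bwd)


def warp_bilinear(img: Tensor, u: Tensor) -> Tensor:
    """Backward-warp ``img`` by displacement field ``u`` (spatial transformer).

    ``img``: (N, C, H, W); ``u``: (N, 2, H, W) in pixel units, channel 0 the
    x- (column) displacement and channel 1 the y- (row) displacement.  The
    output at pixel p samples ``img`` at p + u(p) with bilinear interpolation;
    sample coordinates are clamped to the image border.  Differentiable with
    respect to both ``img`` and ``u``.
    """
    if not np.all(np.isfinite(u.data)):
        raise ValueError("displacement field contains non-finite values")
    n, c, h, w = img.data.shape
    if u.data.shape != (n, 2, h, w):
        raise ValueError(f"displacement field shape {u.data.shape} does not match image {img.data.shape}")
    gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    xs = gx[None] + u.data[:, 0]
    ys = gy[None] + u.data[:, 1]
    # clamp gradient masks before clipping the coordinates
    mx = (xs > 0) & (xs < w - 1)
    my = (ys > 0) & (ys < h - 1)
    xs = np.clip(xs, 0, w - 1)
    ys = np.clip(ys, 0, h - 1)
    x0 = np.floor(xs).astype(np.intp)
    y0 = np.floor(ys).astype(np.intp)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    wx = (xs - x0).astype(img.data.dtype)
    wy = (ys - y0).astype(img.data.dtype)

    flat = img.data.reshape(n, c, h * w)
    idx00 = (y0 * w + x0).reshape(n, 1, h * w)
    idx01 = (y0 * w + x1).reshape(n, 1, h * w)
    idx10 = (y1 * w + x0).reshape(n, 1, h * w)
    idx11 = (y1 * w + x1).reshape(n, 1, h * w)
    i00 = np.take_along_axis(flat, np.broadcast_to(idx00, (n, c, h * w)), axis=2).reshape(n, c, h, w)
    i01 = np.take_along_axis(flat, np.broadcast_to(idx01, (n, c, h * w)), axis=2).reshape(n, c, h, w)
    i10 = np.take_along_axis(flat, np.broadcast_to(idx10, (n, c, h * w)), axis=2).reshape(n, c, h, w)
    i11 = np.take_along_axis(flat, np.broadcast_to(idx11, (n, c, h * w)), axis=2).reshape(n, c, h, w)

    wxe = wx[:, None]
    wye = wy[:, None]
    out = ((1 - wye) * ((1 - wxe) * i00 + wxe * i01) + wye * ((1 - wxe) * i10 + wxe * i11))

    def bwd(g):
        if img.requires_grad:
            size = n * c * h * w
            base = (np.arange(n * c).reshape(n, c, 1, 1) * (h * w))
            dimg = np.zeros(size, dtype=g.dtype)
            for idx, wgt in (
                (y0 * w + x0, (1 - wye) * (1 - wxe)),
                (y0 * w + x1, (1 - wye) * wxe),
                (y1 * w + x0, wye * (1 - wxe)),
                (y1 * w + x1, wye * wxe),
            ):
                full_idx = (base + idx[:, None]).ravel()
                dimg += np.bincount(full_idx, weights=(g * wgt).ravel(), minlength=size)
            img._accum(dimg.reshape(img.data.shape).astype(g.dtype))
        if u.requires_grad:
            dx = ((1 - wye) * (i01 - i00) + wye * (i11 - i10)) * g
            dy = ((1 - wxe) * (i10 - i00) + wxe * (i11 - i01)) * g
            du = np.stack([dx.sum(axis=1) * mx, dy.sum(axis=1) * my], axis=1)
            u._accum(du.astype(g.dtype))

    return Tensor._make(out, (img, u), bwd)
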
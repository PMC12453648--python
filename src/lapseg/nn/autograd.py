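"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine providing exactly the operations the
segmentation network needs: broadcast arithmetic, matmul, 2-D
convolution (im2col), pooling, bilinear resampling, softmax and a few
gather/scatter primitives.  Everything runs in float32.  Gradient
correctness is established by finite-difference checks in the test
suite rather than by construction, so new primitives must ship with a
gradcheck test.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=DTYPE)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _from_op(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- backward pass --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        if not self.requires_grad:
            return
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(DTYPE, copy=True)
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return Tensor._from_op(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._from_op(-self.data, (self,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(g)
            other._accum(-g)

        return Tensor._from_op(self.data - other.data, (self, other), bw)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._from_op(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data * other.data))

        return Tensor._from_op(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        if exponent == 0:  # constant 1; avoid 0 * x**-1 = nan at x = 0
            def bw0(g):
                self._accum(np.zeros_like(self.data))

            return Tensor._from_op(np.ones_like(self.data), (self,), bw0)
        out_data = self.data ** exponent

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._from_op(out_data, (self,), bw)

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        e = np.exp(self.data)

        def bw(g):
            self._accum(g * e)

        return Tensor._from_op(e, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._from_op(np.log(self.data), (self,), bw)

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._from_op(self.data * mask, (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * s * (1.0 - s))

        return Tensor._from_op(s, (self,), bw)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * (s + self.data * s * (1.0 - s)))

        return Tensor._from_op(self.data * s, (self,), bw)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def bw(g):
            self._accum(g * mask)

        return Tensor._from_op(np.clip(self.data, lo, hi), (self,), bw)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor._from_op(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._from_op(self.data.transpose(axes), (self,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape))
            else:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                if not keepdims:
                    g = np.expand_dims(g, axes)
                self._accum(np.broadcast_to(g, shape))

        return Tensor._from_op(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max over a single axis; gradient flows to the (first) argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        shape = self.data.shape

        def bw(g):
            if g.shape != out_data.shape:
                g = g.reshape(out_data.shape)
            gx = np.zeros(shape, dtype=DTYPE)
            np.put_along_axis(gx, np.expand_dims(idx, axis), g, axis=axis)
            self._accum(gx)

        out = Tensor._from_op(
            out_data if keepdims else np.squeeze(out_data, axis), (self,), bw
        )
        return out

    # -- linear algebra -------------------------------------------------------
    def matmul(self, other: "Tensor"):
        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor._from_op(self.data @ other.data, (self, other), bw)

    def __matmul__(self, other):
        return self.matmul(other)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors: list, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        pieces = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, pieces):
            t._accum(p)

    return Tensor._from_op(np.concatenate(datas, axis=axis), tensors, bw)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * p).sum(axis=axis, keepdims=True)
        x._accum(p * (g - dot))

    return Tensor._from_op(p, (x,), bw)


def gather_channel(x: Tensor, index: np.ndarray) -> Tensor:
    """Select x[n, index[n,h,w], h, w] -> (N, 1, H, W).

    Each output element maps to a unique input element, so the scatter
    in the backward pass has no collisions.
    """
    idx = index[:, None, :, :].astype(np.int64)
    out_data = np.take_along_axis(x.data, idx, axis=1)

    def bw(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx, g, axis=1)
        x._accum(gx)

    return Tensor._from_op(out_data, (x,), bw)


def pixel_gather(x: Tensor, n_idx, h_idx, w_idx) -> Tensor:
    """Select full channel vectors at pixels: -> (M, C)."""
    n_idx = np.asarray(n_idx, dtype=np.int64)
    h_idx = np.asarray(h_idx, dtype=np.int64)
    w_idx = np.asarray(w_idx, dtype=np.int64)
    out_data = x.data[n_idx, :, h_idx, w_idx]

    def bw(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (n_idx, slice(None), h_idx, w_idx), g)
        x._accum(gx)

    return Tensor._from_op(out_data, (x,), bw)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int):
    """x (N,C,H,W) -> cols (N*Ho*Wo, C*k*k), plus (Ho, Wo)."""
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,H-k+1,W-k+1,k,k)
    win = win[:, :, ::stride, ::stride, :, :]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation). x (N,C,H,W), w (O,C,k,k), b (O,)."""
    n, c, h, wd = x.data.shape
    o, ci, k, k2 = w.data.shape
    assert ci == c and k == k2
    if k == 1 and stride == 1 and pad == 0:
        return _conv1x1(x, w, b)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    cols, ho, wo = _im2col(xp, k, stride)
    out = cols @ w.data.reshape(o, -1).T + b.data
    out_data = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)

    def bw(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, o)  # (N*Ho*Wo, O)
        w._accum((g2.T @ cols).reshape(w.data.shape))
        b._accum(g2.sum(axis=0))
        if not x.requires_grad:
            return
        # grad wrt x: full correlation of the stride-dilated g with flipped w
        hp, wp = h + 2 * pad, wd + 2 * pad
        gd = np.zeros((n, o, (ho - 1) * stride + 1, (wo - 1) * stride + 1), dtype=DTYPE)
        gd[:, :, ::stride, ::stride] = g
        gdp = np.pad(gd, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
        wf = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,O,k,k)
        colsg, hg, wg = _im2col(gdp, k, 1)
        gxp_part = (colsg @ wf.reshape(c, -1).T).reshape(n, hg, wg, c).transpose(0, 3, 1, 2)
        gxp = np.zeros((n, c, hp, wp), dtype=DTYPE)
        gxp[:, :, :hg, :wg] = gxp_part
        gx = gxp[:, :, pad:pad + h, pad:pad + wd] if pad else gxp
        x._accum(gx)

    return Tensor._from_op(out_data, (x, w, b), bw)


def _conv1x1(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    n, c, h, wd = x.data.shape
    o = w.data.shape[0]
    wm = w.data.reshape(o, c)
    xr = x.data.transpose(0, 2, 3, 1).reshape(-1, c)
    out = xr @ wm.T + b.data
    out_data = out.reshape(n, h, wd, o).transpose(0, 3, 1, 2)

    def bw(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, o)
        w._accum((g2.T @ xr).reshape(w.data.shape))
        b._accum(g2.sum(axis=0))
        if x.requires_grad:
            x._accum((g2 @ wm).reshape(n, h, wd, c).transpose(0, 3, 1, 2))

    return Tensor._from_op(out_data, (x, w, b), bw)


# ---------------------------------------------------------------------------
# pooling / resampling
# ---------------------------------------------------------------------------

def max_pool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2x2 requires even spatial dimensions")
    xw = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xw = xw.reshape(n, c, h // 2, w // 2, 4)
    idx = np.argmax(xw, axis=-1)
    out_data = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gw = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gx = gw.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gx.reshape(n, c, h, w))

    return Tensor._from_op(out_data, (x,), bw)


def _resize_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (half-pixel centers)."""
    a = np.zeros((n_out, n_in), dtype=DTYPE)
    for i in range(n_out):
        s = (i + 0.5) * n_in / n_out - 0.5
        s = min(max(s, 0.0), n_in - 1.0)
        i0 = int(np.floor(s))
        i1 = min(i0 + 1, n_in - 1)
        f = s - i0
        a[i, i0] += 1.0 - f
        a[i, i1] += f
    return a


def resize_bilinear(x: Tensor, size: tuple) -> Tensor:
    ho, wo = size
    n, c, h, w = x.data.shape
    if (ho, wo) == (h, w):
        return x
    ah = _resize_matrix(ho, h)
    aw = _resize_matrix(wo, w)
    out_data = np.matmul(np.matmul(ah, x.data), aw.T)

    def bw(g):
        x._accum(np.matmul(np.matmul(ah.T, g), aw))

    return Tensor._from_op(out_data, (x,), bw)


def reflect_pad2d(x: Tensor, p: int) -> Tensor:
    """Reflect-pad the two trailing axes by p (no edge repetition)."""
    n, c, h, w = x.data.shape
    idx_h = np.pad(np.arange(h), p, mode="reflect")
    idx_w = np.pad(np.arange(w), p, mode="reflect")
    out_data = x.data[:, :, idx_h][:, :, :, idx_w]

    def bw(g):
        # fold padded-axis gradients back onto their source rows/cols
        gh = np.zeros((n, c, h, w + 2 * p), dtype=DTYPE)
        np.add.at(gh.transpose(2, 0, 1, 3), idx_h, g.transpose(2, 0, 1, 3))
        gx = np.zeros((n, c, h, w), dtype=DTYPE)
        np.add.at(gx.transpose(3, 0, 1, 2), idx_w, gh.transpose(3, 0, 1, 2))
        x._accum(gx)

    return Tensor._from_op(out_data, (x,), bw)


def zero_upsample2x(x: Tensor) -> Tensor:
    """Insert zeros between samples (used for transposed-conv upsampling)."""
    n, c, h, w = x.data.shape
    out_data = np.zeros((n, c, 2 * h, 2 * w), dtype=DTYPE)
    out_data[:, :, ::2, ::2] = x.data

    def bw(g):
        x._accum(g[:, :, ::2, ::2])

    return Tensor._from_op(out_data, (x,), bw)
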
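"""Minimal reverse-mode automatic differentiation on numpy arrays.

The blind-spot architecture makes a hard structural promise — the output at
pixel (i, j) is *exactly* independent of the input at (i, j) — and the
cleanest way to state and verify that promise is through true gradients, not
finite differences.  This module provides a small tensor type with the
operations the networks in this package need (broadcast arithmetic,
reductions, 2-D convolution, pooling, dihedral transforms) plus an Adam
optimizer.  It is deliberately tiny: no graphs survive across calls, no
in-place mutation of tracked values, float32 throughout unless the caller
supplies float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "log", "exp", "sqrt", "sigmoid", "softplus",
           "maximum", "clip", "concat", "conv2d", "maxpool2x2", "upsample2x",
           "rot90", "flip", "shift_rows", "pad2d", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    # make numpy defer to the reflected operators instead of coercing
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False,
                 parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
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

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.result_type(self.data, np.float32))
        self.grad += g

    def backward(self, grad=None):
        """Reverse-mode sweep from this tensor (scalar unless grad given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() on non-scalar requires an explicit gradient")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = bwd if out.requires_grad else None
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd if out.requires_grad else None
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
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(
                    -g * self.data / (other.data ** 2), other.data.shape))
        out._backward = bwd if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))
        out._backward = bwd if out.requires_grad else None
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)
        out._backward = bwd if out.requires_grad else None
        return out

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))
        out._backward = bwd if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
        out._backward = bwd if out.requires_grad else None
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        shape = self.data.shape

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape).astype(self.data.dtype))
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, shape).astype(self.data.dtype))
        out._backward = bwd if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ----------------------------------------------------------------- pointwise
def _unary(x: Tensor, fwd, dfdx) -> Tensor:
    x = as_tensor(x)
    y = fwd(x.data)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * dfdx(x.data, y))
    out._backward = bwd if out.requires_grad else None
    return out


def log(x):
    if not isinstance(x, Tensor):
        return np.log(x)
    return _unary(x, np.log, lambda d, y: 1.0 / d)


def exp(x):
    if not isinstance(x, Tensor):
        return np.exp(x)
    return _unary(x, np.exp, lambda d, y: y)


def sqrt(x):
    if not isinstance(x, Tensor):
        return np.sqrt(x)
    return _unary(x, np.sqrt, lambda d, y: 0.5 / y)


def _expit(d):
    # overflow-safe logistic
    out = np.empty_like(d, dtype=np.result_type(d, np.float32))
    pos = d >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    ed = np.exp(d[~pos])
    out[~pos] = ed / (1.0 + ed)
    return out


def sigmoid(x):
    if not isinstance(x, Tensor):
        return _expit(np.asarray(x))
    return _unary(x, lambda d: _expit(d), lambda d, y: y * (1.0 - y))


def softplus(x):
    def f(d):
        # overflow-safe: softplus(d) = max(d,0) + log1p(exp(-|d|))
        return np.maximum(d, 0.0) + np.log1p(np.exp(-np.abs(d)))
    if not isinstance(x, Tensor):
        return f(x)
    return _unary(x, f, lambda d, y: _expit(d))


def leaky_relu(x, slope: float = 0.1):
    if not isinstance(x, Tensor):
        return np.where(x > 0, x, slope * x)
    return _unary(x, lambda d: np.where(d > 0, d, slope * d),
                  lambda d, y: np.where(d > 0, 1.0, slope))


def maximum(x, other):
    """Elementwise max; gradient flows to `x` where x >= other (numpy or Tensor)."""
    if not isinstance(x, Tensor) and not isinstance(other, Tensor):
        return np.maximum(x, other)
    x = as_tensor(x)
    oth = other.data if isinstance(other, Tensor) else np.asarray(other)
    out = Tensor(np.maximum(x.data, oth),
                 parents=(x, other) if isinstance(other, Tensor) else (x,))
    mask = x.data >= oth

    def bwd(g):
        if x.requires_grad:
            x._accumulate(_unbroadcast(g * mask, x.data.shape))
        if isinstance(other, Tensor) and other.requires_grad:
            other._accumulate(_unbroadcast(g * ~mask, other.data.shape))
    out._backward = bwd if out.requires_grad else None
    return out


def clip(x, lo: float, hi: float):
    """Clamp; zero gradient outside [lo, hi]."""
    if not isinstance(x, Tensor):
        return np.clip(x, lo, hi)
    return _unary(x, lambda d: np.clip(d, lo, hi),
                  lambda d, y: ((d >= lo) & (d <= hi)).astype(d.dtype))


# ------------------------------------------------------------------ shaping
def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def bwd(g):
        splits = np.cumsum(sizes)[:-1]
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)
    out._backward = bwd if out.requires_grad else None
    return out


def rot90(x, k: int, axes=(1, 2)):
    """Quarter-turn rotation in the spatial plane (default NHWC layout)."""
    if not isinstance(x, Tensor):
        return np.ascontiguousarray(np.rot90(x, k, axes=axes))
    out = Tensor(np.ascontiguousarray(np.rot90(x.data, k, axes=axes)), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.ascontiguousarray(np.rot90(g, -k, axes=axes)))
    out._backward = bwd if out.requires_grad else None
    return out


def flip(x, axis: int):
    if not isinstance(x, Tensor):
        return np.ascontiguousarray(np.flip(x, axis=axis))
    out = Tensor(np.ascontiguousarray(np.flip(x.data, axis=axis)), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.ascontiguousarray(np.flip(g, axis=axis)))
    out._backward = bwd if out.requires_grad else None
    return out


def shift_rows(x: Tensor, n: int) -> Tensor:
    """Shift image content down by `n` rows, zero-filling at the top (NHWC).

    This is the causality shim of the blind-spot construction: after a stack
    of vertically causal ops (receptive field rows <= i) one downward shift
    makes the receptive field strictly above the output pixel.
    """
    x = as_tensor(x)
    if n == 0:
        return x
    H = x.data.shape[1]
    y = np.zeros_like(x.data)
    y[:, n:, :, :] = x.data[:, :H - n, :, :]
    out = Tensor(y, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[:, :H - n, :, :] = g[:, n:, :, :]
            x._accumulate(gx)
    out._backward = bwd if out.requires_grad else None
    return out


def pad2d(x: Tensor, pads) -> Tensor:
    """Zero-pad spatial dims of an NHWC tensor; pads = (top, bottom, left, right)."""
    x = as_tensor(x)
    pt, pb, pl, pr = pads
    out = Tensor(np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0))), parents=(x,))
    H, W = x.data.shape[1], x.data.shape[2]

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g[:, pt:pt + H, pl:pl + W, :])
    out._backward = bwd if out.requires_grad else None
    return out


# --------------------------------------------------------------- convolution
def conv2d(x: Tensor, w: Tensor, b: Tensor, pads) -> Tensor:
    """2-D convolution, NHWC activations, (cin, kh, kw, cout) weights.

    `pads` = (top, bottom, left, right) zero padding; output spatial size is
    H + pt + pb - kh + 1 (same-size for symmetric pads with odd kernels, and
    vertically causal for (kh-1, 0) padding).  Implemented as im2col + one
    GEMM; the column matrix is kept for the weight-gradient GEMM and freed
    with the graph.
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    cin, kh, kw, cout = w.data.shape
    pt, pb, pl, pr = pads
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    N, Hp, Wp, _ = xp.shape
    H2, W2 = Hp - kh + 1, Wp - kw + 1
    if kh == kw == 1:
        # pointwise: no column matrix needed
        wmat = w.data.reshape(cin, cout)
        out = Tensor((xp.reshape(-1, cin) @ wmat + b.data).reshape(
            N, H2, W2, cout), parents=(x, w, b))

        def bwd1(g):
            gm = g.reshape(-1, cout)
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 1, 2)))
            if w.requires_grad:
                w._accumulate((xp.reshape(-1, cin).T @ gm).reshape(w.data.shape))
            if x.requires_grad:
                x._accumulate((gm @ wmat.T).reshape(xp.shape))
        out._backward = bwd1 if out.requires_grad else None
        return out
    # im2col + GEMM, chunked over the batch so the column block stays cache-sized
    kdim = cin * kh * kw
    wmat = w.data.reshape(kdim, cout)
    per_img = H2 * W2 * kdim * 4
    chunk = max(1, int(6_000_000 // max(per_img, 1)))

    def make_cols(lo, hi):
        win = np.lib.stride_tricks.sliding_window_view(
            xp[lo:hi].transpose(0, 3, 1, 2), (kh, kw), axis=(2, 3))
        return win.transpose(0, 2, 3, 1, 4, 5).reshape((hi - lo) * H2 * W2, kdim)

    out_data = np.empty((N, H2, W2, cout), dtype=np.result_type(x.data, w.data))
    for lo in range(0, N, chunk):
        hi = min(N, lo + chunk)
        out_data[lo:hi] = (make_cols(lo, hi) @ wmat).reshape(
            hi - lo, H2, W2, cout)
    out_data += b.data
    out = Tensor(out_data, parents=(x, w, b))

    def bwd(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        gw = np.zeros((kdim, cout), dtype=w.data.dtype) if w.requires_grad else None
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for lo in range(0, N, chunk):
            hi = min(N, lo + chunk)
            gm = g[lo:hi].reshape(-1, cout)
            cols = make_cols(lo, hi) if w.requires_grad else None
            if gw is not None:
                gw += cols.T @ gm
            if gxp is not None:
                dcols = (gm @ wmat.T).reshape(hi - lo, H2, W2, cin, kh, kw)
                for a in range(kh):
                    for c in range(kw):
                        gxp[lo:hi, a:a + H2, c:c + W2, :] += dcols[:, :, :, :, a, c]
        if gw is not None:
            w._accumulate(gw.reshape(w.data.shape))
        if gxp is not None:
            x._accumulate(gxp[:, pt:pt + x.data.shape[1],
                              pl:pl + x.data.shape[2], :])
    out._backward = bwd if out.requires_grad else None
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, NHWC; ties resolved to the first (row-major) element."""
    x = as_tensor(x)
    N, H, W, C = x.data.shape
    xr = x.data.reshape(N, H // 2, 2, W // 2, 2, C)
    xf = xr.transpose(0, 1, 3, 5, 2, 4).reshape(N, H // 2, W // 2, C, 4)
    idx = np.argmax(xf, axis=-1)
    out_data = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, parents=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        gf = np.zeros((N, H // 2, W // 2, C, 4), dtype=g.dtype)
        np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
        gx = gf.reshape(N, H // 2, W // 2, C, 2, 2).transpose(
            0, 1, 4, 2, 5, 3).reshape(N, H, W, C)
        x._accumulate(gx)
    out._backward = bwd if out.requires_grad else None
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling, NHWC."""
    x = as_tensor(x)
    N, H, W, C = x.data.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g.reshape(N, H, 2, W, 2, C).sum(axis=(2, 4)))
    out._backward = bwd if out.requires_grad else None
    return out


# ---------------------------------------------------------------- optimizer
class Adam:
    """Adam with per-step learning rate (schedules pass lr to step())."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
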
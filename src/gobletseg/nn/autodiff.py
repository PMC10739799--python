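"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A ``Tensor`` wraps a float64 ndarray and records its parents plus a closure
that propagates the upstream gradient. ``Tensor.backward`` runs a reverse
topological sweep. Only the primitives the segmentation networks and losses
need are provided: broadcast arithmetic, elementwise nonlinearities,
reductions, 2-D convolution (via im2col/matmul), 2x2 transposed convolution,
2x2 max-pooling, x2 bilinear upsampling, batch normalization and channel
concatenation. Feature maps are laid out NCHW.

Gradients of every primitive are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat_channels", "conv2d", "conv_transpose2x2",
           "maxpool2x2", "upsample_bilinear2x", "batchnorm2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False,
                 parents=(), backward=None, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad only on scalars")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
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
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            self._accum(g)
            other._accum(g)
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def pow_const(self, exponent: float) -> "Tensor":
        """Elementwise power with a constant, non-negative base assumed."""
        out = Tensor(self.data**exponent, parents=(self,))

        def bw(g):
            if exponent == 0:
                return
            with np.errstate(divide="ignore", invalid="ignore"):
                d = exponent * self.data ** (exponent - 1)
            self._accum(g * np.where(np.isfinite(d), d, 0.0))
        out._backward = bw
        return out

    # -- nonlinearities ---------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp; gradient passes only through unclipped entries."""
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        inside = (self.data > lo) & (self.data < hi)
        out._backward = lambda g: self._accum(g * inside)
        return out

    # -- reductions / reshaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def spatial_mean(self) -> "Tensor":
        """Per-channel global average pool: (N,C,H,W) -> (N,C,1,1)."""
        return self.mean(axis=(2, 3), keepdims=True)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out


def concat_channels(tensors: list[Tensor]) -> Tensor:
    """Concatenate NCHW tensors along the channel axis."""
    data = np.concatenate([t.data for t in tensors], axis=1)
    out = Tensor(data, parents=tuple(tensors))
    splits = np.cumsum([t.data.shape[1] for t in tensors])[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=1)):
            t._accum(piece)
    out._backward = bw
    return out


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N,Ho,Wo,C,kh,kw) view of sliding windows."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]                   # (N,C,Ho,Wo,kh,kw)
    return np.transpose(win, (0, 2, 3, 1, 4, 5))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None,
           stride: tuple[int, int] = (1, 1),
           padding: tuple[int, int] = (0, 0)) -> Tensor:
    """2-D cross-correlation; x:(N,Cin,H,W), w:(Cout,Cin,kh,kw), b:(Cout,)."""
    sh, sw = stride
    ph, pw = padding
    n, cin, h, wd = x.data.shape
    cout, cin2, kh, kw = w.data.shape
    if cin != cin2:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = _im2col(xp, kh, kw, sh, sw)            # (N,Ho,Wo,Cin,kh,kw)
    n_, ho, wo = cols.shape[:3]
    cols2 = cols.reshape(n * ho * wo, cin * kh * kw)
    wf = w.data.reshape(cout, cin * kh * kw)
    y = cols2 @ wf.T
    if b is not None:
        y = y + b.data
    y = y.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(np.ascontiguousarray(y), parents=parents)

    def bw(g):
        gflat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        if w.requires_grad:
            w._accum((gflat.T @ cols2).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gflat.sum(axis=0))
        if x.requires_grad:
            gcols = (gflat @ wf).reshape(n, ho, wo, cin, kh, kw)
            gcols = np.transpose(gcols, (0, 3, 1, 2, 4, 5))  # (N,Cin,Ho,Wo,kh,kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += gcols[..., i, j]
            if ph or pw:
                gxp = gxp[:, :, ph:ph + h, pw:pw + wd]
            x._accum(gxp)
    out._backward = bw
    return out


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2 stride-2 transposed convolution (non-overlapping up-convolution).

    x:(N,Cin,H,W), w:(Cin,Cout,2,2) -> (N,Cout,2H,2W).
    """
    n, cin, h, wd = x.data.shape
    cin2, cout = w.data.shape[:2]
    if cin != cin2:
        raise ValueError("channel mismatch in transposed convolution")
    t = np.tensordot(x.data, w.data, axes=([1], [0]))  # (N,H,W,Cout,2,2)
    y = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, cout, 2 * h, 2 * wd)
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(np.ascontiguousarray(y), parents=parents)

    def bw(g):
        gt = g.reshape(n, cout, h, 2, wd, 2).transpose(0, 2, 4, 1, 3, 5)
        if x.requires_grad:
            x._accum(np.tensordot(gt, w.data, axes=([3, 4, 5], [1, 2, 3]))
                     .transpose(0, 3, 1, 2))
        if w.requires_grad:
            w._accum(np.tensordot(x.data, gt, axes=([0, 2, 3], [0, 1, 2])))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
    out._backward = bw
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max-pooling with stride 2; spatial dims must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    v = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    flat = v.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0],
                 parents=(x,))

    def bw(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gx.reshape(n, c, h, w))
    out._backward = bw
    return out


def _lin_coeffs(n_out: int, n_in: int):
    """Bilinear x2 sampling coefficients along one axis (half-pixel centers)."""
    src = (np.arange(n_out) + 0.5) / 2.0 - 0.5
    i0 = np.floor(src).astype(int)
    frac = src - i0
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    i0 = np.clip(i0, 0, n_in - 1)
    return i0, i1, frac


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear x2 upsampling of an NCHW tensor (half-pixel alignment)."""
    n, c, h, w = x.data.shape
    r0, r1, fr = _lin_coeffs(2 * h, h)
    c0, c1, fc = _lin_coeffs(2 * w, w)
    def interp(a):
        rows = a[:, :, r0, :] * (1 - fr)[None, None, :, None] \
             + a[:, :, r1, :] * fr[None, None, :, None]
        return rows[:, :, :, c0] * (1 - fc)[None, None, None, :] \
             + rows[:, :, :, c1] * fc[None, None, None, :]

    out = Tensor(interp(x.data), parents=(x,))

    def bw(g):
        # transpose of the two 1-D linear maps, applied in reverse order
        rows_acc = np.zeros((n, c, 2 * h, w))
        gw0 = g * (1 - fc)[None, None, None, :]
        gw1 = g * fc[None, None, None, :]
        np.add.at(rows_acc, (slice(None), slice(None), slice(None), c0), gw0)
        np.add.at(rows_acc, (slice(None), slice(None), slice(None), c1), gw1)
        gx = np.zeros((n, c, h, w))
        gr0 = rows_acc * (1 - fr)[None, None, :, None]
        gr1 = rows_acc * fr[None, None, :, None]
        np.add.at(gx, (slice(None), slice(None), r0), gr0)
        np.add.at(gx, (slice(None), slice(None), r1), gr1)
        x._accum(gx)
    out._backward = bw
    return out


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization of an NCHW tensor.

    In training mode batch statistics normalize and update the running
    buffers in place; in eval mode the running statistics are used.
    """
    n, c, h, w = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = Tensor(y, parents=(x, gamma, beta))
    m = n * h * w

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxh = g * gamma.data[None, :, None, None]
            if training:
                s1 = gxh.sum(axis=(0, 2, 3))[None, :, None, None]
                s2 = (gxh * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
                gx = (gxh - s1 / m - xhat * s2 / m) * inv[None, :, None, None]
            else:
                gx = gxh * inv[None, :, None, None]
            x._accum(gx)
    out._backward = bw
    return out
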
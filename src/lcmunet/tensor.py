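"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation networks in this package are expressed over a small set of
array operations (convolutions, normalisations, pointwise nonlinearities,
resampling).  Each operation builds a node in a dynamic computation graph;
``Tensor.backward`` releases gradients by reverse topological traversal.
Data is kept in float32 throughout.

A process-global multiply-accumulate counter can be armed with
:func:`count_macs`; while active, every convolution / linear op adds its MAC
cost (the ``k^2 * C_in/groups * C_out * H_out * W_out`` profiler convention),
which is how the complexity module traces FLOPs through a real forward pass.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = [
    "Tensor", "Parameter", "count_macs",
    "relu", "sigmoid", "gelu", "log",
    "conv2d", "conv_transpose2d", "linear",
    "batch_norm2d", "layer_norm_channels",
    "max_pool2x2", "upsample_bilinear2x", "axial_shift",
    "global_avg_pool", "scale_channels", "tsum", "tmean", "clip",
]

_mac_counter: list = []


@contextlib.contextmanager
def count_macs():
    """Context manager yielding a one-element list accumulating MACs."""
    box = [0]
    _mac_counter.append(box)
    try:
        yield box
    finally:
        for i, other in enumerate(_mac_counter):
            if other is box:
                del _mac_counter[i]
                break


def _add_macs(n: int) -> None:
    for box in _mac_counter:
        box[0] += int(n)


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
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

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out


class Parameter(Tensor):
    """A trainable tensor (requires_grad is always on)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Iterable[Tensor]) -> Tensor:
    return Tensor(data, parents=tuple(parents))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# pointwise nonlinearities
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = _node(np.maximum(x.data, 0.0), (x,))
    out._backward = lambda g: x._accumulate(g * (x.data > 0))
    return out


def sigmoid(x: Tensor) -> Tensor:
    # split by sign so exp never overflows
    pos = x.data >= 0
    e = np.exp(np.where(pos, -x.data, x.data))
    s = np.where(pos, 1.0 / (1.0 + e), e / (1.0 + e)).astype(np.float32)
    out = _node(s, (x,))
    out._backward = lambda g: x._accumulate(g * s * (1.0 - s))
    return out


_INV_SQRT2 = np.float32(1.0 / np.sqrt(2.0))
_INV_SQRT2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    cdf = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))
    out = _node(x.data * cdf, (x,))

    def bw(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data * x.data)
        x._accumulate(g * (cdf + x.data * pdf))
    out._backward = bw
    return out


def log(x: Tensor) -> Tensor:
    out = _node(np.log(x.data), (x,))
    out._backward = lambda g: x._accumulate(g / x.data)
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    out = _node(np.clip(x.data, lo, hi), (x,))
    mask = (x.data > lo) & (x.data < hi)
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def tsum(x: Tensor) -> Tensor:
    out = _node(np.array(x.data.sum(), dtype=np.float32), (x,))
    out._backward = lambda g: x._accumulate(np.broadcast_to(g, x.shape).astype(np.float32))
    return out


def tmean(x: Tensor) -> Tensor:
    n = x.data.size
    out = _node(np.array(x.data.mean(), dtype=np.float32), (x,))
    out._backward = lambda g: x._accumulate(
        np.broadcast_to(g / n, x.shape).astype(np.float32))
    return out


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------

def _pad_nchw(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, padding: tuple[int, int] = (0, 0),
           groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (C_out, C_in/g, kh, kw)."""
    N, C, H, W = x.shape
    Co, Cg, kh, kw = w.shape
    if C != Cg * groups:
        raise ValueError(f"channel mismatch: input has {C}, weight expects {Cg * groups}")
    ph, pw = padding
    s = stride
    Ho = (H + 2 * ph - kh) // s + 1
    Wo = (W + 2 * pw - kw) // s + 1
    xp = _pad_nchw(x.data, ph, pw)
    depthwise = groups == C and Cg == 1 and Co == C

    if depthwise:
        # shift-and-accumulate: cheap in memory, vectorised over channels
        out = np.zeros((N, C, Ho, Wo), dtype=np.float32)
        for ki in range(kh):
            for kj in range(kw):
                out += xp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s] \
                    * w.data[:, 0, ki, kj][None, :, None, None]
        cols = None
    elif kh == 1 and kw == 1 and s == 1 and groups == 1:
        # pointwise conv as a channel matmul
        out = np.matmul(w.data.reshape(Co, C),
                        xp.reshape(N, C, H * W)).reshape(N, Co, Ho, Wo)
        cols = None
    else:
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, Ho, Wo, kh, kw) -> (N*Ho*Wo, g, Cg*kh*kw)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, groups, Cg * kh * kw)
        wg = w.data.reshape(groups, Co // groups, Cg * kh * kw)
        out = np.einsum("pgk,gok->pgo", cols, wg, optimize=True)
        out = out.reshape(N, Ho, Wo, Co).transpose(0, 3, 1, 2).copy()

    if b is not None:
        out += b.data[None, :, None, None]
    _add_macs(kh * kw * Cg * Co * Ho * Wo)

    parents = (x, w) if b is None else (x, w, b)
    res = _node(out, parents)

    def bw(g):
        g = np.ascontiguousarray(g, dtype=np.float32)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if depthwise:
            dw = np.zeros_like(w.data)
            for ki in range(kh):
                for kj in range(kw):
                    dw[:, 0, ki, kj] = (
                        g * xp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s]
                    ).sum(axis=(0, 2, 3))
            w._accumulate(dw)
        elif cols is None:
            gw = np.matmul(g.reshape(N, Co, H * W),
                           xp.reshape(N, C, H * W).transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(gw.reshape(w.shape))
        else:
            gp = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, groups, Co // groups)
            dwg = np.einsum("pgo,pgk->gok", gp, cols, optimize=True)
            w._accumulate(dwg.reshape(w.shape))
        if x.requires_grad or x._parents:
            dxp = np.zeros_like(xp)
            if depthwise:
                for ki in range(kh):
                    for kj in range(kw):
                        dxp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s] += \
                            g * w.data[:, 0, ki, kj][None, :, None, None]
            elif cols is None:
                dxp += np.matmul(w.data.reshape(Co, C).T,
                                 g.reshape(N, Co, H * W)).reshape(N, C, H, W)
            else:
                wg = w.data.reshape(groups, Co // groups, Cg, kh, kw)
                gg = g.reshape(N, groups, Co // groups, Ho, Wo)
                for ki in range(kh):
                    for kj in range(kw):
                        contrib = np.einsum("ngohw,goc->ngchw", gg,
                                            wg[:, :, :, ki, kj], optimize=True)
                        dxp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s] += \
                            contrib.reshape(N, C, Ho, Wo)
            if ph or pw:
                dxp = dxp[:, :, ph:ph + H, pw:pw + W]
            x._accumulate(dxp)
    res._backward = bw
    return res


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2x2 / stride 2 (weight (C_in, C_out, 2, 2))."""
    N, C, H, W = x.shape
    Ci, Co, kh, kw = w.shape
    if (kh, kw) != (2, 2):
        raise NotImplementedError("only 2x2 stride-2 transposed convolutions")
    if Ci != C:
        raise ValueError("channel mismatch in transposed convolution")
    out = np.einsum("ncij,coab->noiajb", x.data, w.data,
                    optimize=True).reshape(N, Co, 2 * H, 2 * W).copy()
    if b is not None:
        out += b.data[None, :, None, None]
    _add_macs(kh * kw * Ci * Co * (2 * H) * (2 * W))
    parents = (x, w) if b is None else (x, w, b)
    res = _node(out, parents)

    def bw(g):
        g6 = g.reshape(N, Co, H, 2, W, 2)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        w._accumulate(np.einsum("ncij,noiajb->coab", x.data, g6, optimize=True))
        if x.requires_grad or x._parents:
            x._accumulate(np.einsum("noiajb,coab->ncij", g6, w.data, optimize=True))
    res._backward = bw
    return res


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Affine map on the last axis; weight (out_features, in_features)."""
    out = x.data @ w.data.T
    if b is not None:
        out = out + b.data
    _add_macs(w.data.size * (x.data.size // x.shape[-1]))
    parents = (x, w) if b is None else (x, w, b)
    res = _node(out, parents)

    def bw(g):
        if b is not None:
            b._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))
        g2 = g.reshape(-1, g.shape[-1])
        x2 = x.data.reshape(-1, x.shape[-1])
        w._accumulate(g2.T @ x2)
        if x.requires_grad or x._parents:
            x._accumulate((g @ w.data).reshape(x.shape))
    res._backward = bw
    return res


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray, *,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N, H, W) per channel; updates running stats in place."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = x.data.size // x.shape[1]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]
    res = _node(out.astype(np.float32), (x, gamma, beta))

    def bw(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        if not (x.requires_grad or x._parents):
            return
        gi = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
        if training:
            m = x.data.size // x.shape[1]
            gm = g.mean(axis=(0, 2, 3))[None, :, None, None]
            gxm = (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
            x._accumulate(gi * (g - gm - xhat * gxm))
        else:
            x._accumulate(gi * g)
    res._backward = bw
    return res


def layer_norm_channels(x: Tensor, gamma: Tensor, beta: Tensor,
                        eps: float = 1e-5) -> Tensor:
    """Layer normalisation across the channel axis of an NCHW map."""
    mean = x.data.mean(axis=1, keepdims=True)
    var = x.data.var(axis=1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv_std
    out = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]
    res = _node(out.astype(np.float32), (x, gamma, beta))

    def bw(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        if not (x.requires_grad or x._parents):
            return
        gg = g * gamma.data[None, :, None, None]
        gm = gg.mean(axis=1, keepdims=True)
        gxm = (gg * xhat).mean(axis=1, keepdims=True)
        x._accumulate(inv_std * (gg - gm - xhat * gxm))
    res._backward = bw
    return res


# ---------------------------------------------------------------------------
# resampling and spatial ops
# ---------------------------------------------------------------------------

def max_pool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"max_pool2x2 requires even spatial size, got {H}x{W}")
    win = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(N, C, H // 2, W // 2, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    res = _node(out, (x,))

    def bw(g):
        gw = np.zeros((N, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gw = gw.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gw.reshape(N, C, H, W))
    res._backward = bw
    return res


_bilinear_cache: dict[int, np.ndarray] = {}


def _bilinear_matrix(n: int) -> np.ndarray:
    """Dense (2n x n) matrix of x2 bilinear upsampling (half-pixel centres)."""
    if n not in _bilinear_cache:
        M = np.zeros((2 * n, n), dtype=np.float32)
        for o in range(2 * n):
            src = (o + 0.5) / 2.0 - 0.5
            i0 = int(np.floor(src))
            t = src - i0
            i0c = min(max(i0, 0), n - 1)
            i1c = min(max(i0 + 1, 0), n - 1)
            M[o, i0c] += 1.0 - t
            M[o, i1c] += t
        _bilinear_cache[n] = M
    return _bilinear_cache[n]


def upsample_bilinear2x(x: Tensor) -> Tensor:
    N, C, H, W = x.shape
    Mh, Mw = _bilinear_matrix(H), _bilinear_matrix(W)
    # apply along H then W with BLAS matmuls
    y = np.tensordot(x.data, Mh, axes=([2], [1]))        # N,C,W,2H
    y = np.tensordot(y, Mw, axes=([2], [1]))             # N,C,2H,2W
    res = _node(np.ascontiguousarray(y), (x,))

    def bw(g):
        gy = np.tensordot(g, Mw, axes=([3], [0]))        # N,C,2H,W
        gx = np.tensordot(gy.transpose(0, 1, 3, 2), Mh, axes=([3], [0]))
        x._accumulate(np.ascontiguousarray(gx.transpose(0, 1, 3, 2)))
    res._backward = bw
    return res


def axial_shift(x: Tensor, offsets: np.ndarray, axis: int) -> Tensor:
    """Shift channel groups along a spatial axis, zero-filling vacated pixels.

    ``offsets`` gives one integer displacement per channel; ``axis`` is 2
    (height) or 3 (width).
    """
    if axis not in (2, 3):
        raise ValueError("axis must be 2 (height) or 3 (width)")
    n = x.shape[axis]
    out = np.zeros_like(x.data)
    for off in np.unique(offsets):
        ch = np.where(offsets == off)[0]
        sl_src = [slice(None)] * 4
        sl_dst = [slice(None)] * 4
        sl_src[1] = ch
        sl_dst[1] = ch
        if off >= 0:
            sl_dst[axis] = slice(off, n)
            sl_src_ax = slice(0, n - off)
        else:
            sl_dst[axis] = slice(0, n + off)
            sl_src_ax = slice(-off, n)
        src = x.data[tuple(sl_src)]
        tmp = np.zeros_like(src)
        sl = [slice(None)] * 4
        sl[axis] = sl_dst[axis]
        sl2 = [slice(None)] * 4
        sl2[axis] = sl_src_ax
        tmp[tuple(sl)] = src[tuple(sl2)]
        out[:, ch] = tmp
    res = _node(out, (x,))

    def bw(g):
        gx = np.zeros_like(x.data)
        for off in np.unique(offsets):
            ch = np.where(offsets == off)[0]
            gsub = g[:, ch]
            tmp = np.zeros_like(gsub)
            if off >= 0:
                sl_d = [slice(None)] * 4
                sl_d[axis] = slice(0, n - off)
                sl_s = [slice(None)] * 4
                sl_s[axis] = slice(off, n)
            else:
                sl_d = [slice(None)] * 4
                sl_d[axis] = slice(-off, n)
                sl_s = [slice(None)] * 4
                sl_s[axis] = slice(0, n + off)
            tmp[tuple(sl_d)] = gsub[tuple(sl_s)]
            gx[:, ch] = tmp
        x._accumulate(gx)
    res._backward = bw
    return res


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the spatial axes: (N, C, H, W) -> (N, C)."""
    N, C, H, W = x.shape
    out = x.data.mean(axis=(2, 3))
    res = _node(out, (x,))

    def bw(g):
        x._accumulate(np.broadcast_to(
            g[:, :, None, None] / (H * W), x.shape).astype(np.float32))
    res._backward = bw
    return res


def scale_channels(x: Tensor, s: Tensor) -> Tensor:
    """Multiply an NCHW map by per-sample per-channel weights (N, C)."""
    out = x.data * s.data[:, :, None, None]
    res = _node(out, (x, s))

    def bw(g):
        s._accumulate((g * x.data).sum(axis=(2, 3)))
        if x.requires_grad or x._parents:
            x._accumulate(g * s.data[:, :, None, None])
    res._backward = bw
    return res
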
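"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network layers in this package are built from a small set of real-valued
array operations (convolution, pooling, resampling, pointwise nonlinearities,
FFTs).  Complex-valued layers are expressed as pairs of real tensors, so the
gradients produced here are exactly the split (Wirtinger-equivalent) gradients:
each complex layer is differentiated as a real computation on paired channels.

Tensors carry float64 data by default.  The graph is built eagerly; calling
:meth:`Tensor.backward` on a scalar loss runs a topological sweep.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: Sequence["Tensor"] = (),
                 _backward: Optional[Callable[[np.ndarray], None]] = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        g = np.asarray(g, dtype=np.float64)
        if g.shape != self.data.shape:  # reduce broadcast axes
            g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient `g` down to `shape` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _node(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, _parents=parents,
                  _backward=backward if req else None)


# -- pointwise ops ---------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bw(g):
        if a.requires_grad or a._parents:
            a._accumulate(g)
        if b.requires_grad or b._parents:
            b._accumulate(g)

    return _node(out_data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def bw(g):
        if a.requires_grad or a._parents:
            a._accumulate(g * b.data)
        if b.requires_grad or b._parents:
            b._accumulate(g * a.data)

    return _node(out_data, (a, b), bw)


def relu(x) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0

    def bw(g):
        x._accumulate(g * mask)

    # np.maximum (not where) so non-finite activations propagate to the loss
    return _node(np.maximum(x.data, 0.0), (x,), bw)


def sigmoid(x) -> Tensor:
    x = _as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        x._accumulate(g * s * (1.0 - s))

    return _node(s, (x,), bw)


def square(x) -> Tensor:
    x = _as_tensor(x)

    def bw(g):
        x._accumulate(g * 2.0 * x.data)

    return _node(x.data ** 2, (x,), bw)


def mean(x) -> Tensor:
    x = _as_tensor(x)
    n = x.data.size

    def bw(g):
        x._accumulate(np.full_like(x.data, float(g) / n))

    return _node(x.data.mean(), (x,), bw)


def tsum(x) -> Tensor:
    x = _as_tensor(x)

    def bw(g):
        x._accumulate(np.full_like(x.data, float(g)))

    return _node(x.data.sum(), (x,), bw)


# -- shape ops -------------------------------------------------------------

def reshape(x, shape) -> Tensor:
    x = _as_tensor(x)
    out_data = x.data.reshape(shape)

    def bw(g):
        x._accumulate(g.reshape(x.data.shape))

    return _node(out_data, (x,), bw)



def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _node(out_data, tuple(tensors), bw)


def crop_axis1(x, start: int, length: int) -> Tensor:
    """Contiguous slice along axis 1 (channels)."""
    x = _as_tensor(x)
    sl = (slice(None), slice(start, start + length))

    def bw(g):
        gx = np.zeros_like(x.data)
        gx[sl] = g
        x._accumulate(gx)

    return _node(np.ascontiguousarray(x.data[sl]), (x,), bw)


def pad2d(x, pad: tuple[int, int, int, int], mode: str = "constant") -> Tensor:
    """Pad the two trailing axes by (top, bottom, left, right)."""
    x = _as_tensor(x)
    t, b, l, r = pad
    widths = [(0, 0)] * (x.ndim - 2) + [(t, b), (l, r)]
    out_data = np.pad(x.data, widths, mode=mode)
    H, W = x.data.shape[-2:]

    def bw(g):
        if mode == "constant":
            sl = (Ellipsis, slice(t, t + H), slice(l, l + W))
            x._accumulate(g[sl])
        else:  # reflect: scatter-add via adjoint of the padding index map
            idx_h = _pad_index(H, t, b, mode)
            idx_w = _pad_index(W, l, r, mode)
            gh = np.zeros(x.data.shape[:-2] + (H, g.shape[-1]), dtype=g.dtype)
            np.add.at(gh, (Ellipsis, idx_h, slice(None)), g)
            gx = np.zeros_like(x.data)
            np.add.at(gx, (Ellipsis, slice(None), idx_w), gh)
            x._accumulate(gx)

    return _node(out_data, (x,), bw)


def _pad_index(n: int, lo: int, hi: int, mode: str) -> np.ndarray:
    base = np.arange(-lo, n + hi)
    if mode == "reflect":
        period = 2 * (n - 1) if n > 1 else 1
        base = np.abs(base) % period
        base = np.where(base >= n, period - base, base)
        return base
    raise ValueError(f"unsupported pad mode {mode!r}")


def crop2d(x, top: int, left: int, height: int, width: int) -> Tensor:
    x = _as_tensor(x)
    sl = (Ellipsis, slice(top, top + height), slice(left, left + width))

    def bw(g):
        gx = np.zeros_like(x.data)
        gx[sl] = g
        x._accumulate(gx)

    return _node(x.data[sl], (x,), bw)


def roll2d(x, shift_h: int, shift_w: int) -> Tensor:
    """Circular shift of the two trailing axes (a permutation; adjoint = inverse roll)."""
    x = _as_tensor(x)
    out_data = np.roll(x.data, (shift_h, shift_w), axis=(-2, -1))

    def bw(g):
        x._accumulate(np.roll(g, (-shift_h, -shift_w), axis=(-2, -1)))

    return _node(out_data, (x,), bw)


# -- convolution -----------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           stride: int = 1, padding: str = "same") -> Tensor:
    """2-D cross-correlation over [B, C, H, W] with kernels [O, C, kh, kw].

    `padding` is "same" (zero padding, odd kernels) or "valid".
    """
    x, w = _as_tensor(x), _as_tensor(w)
    if x.ndim != 4:
        raise ValueError(f"conv2d input must be 4-D [B,C,H,W], got shape {x.shape}")
    O, C, kh, kw = w.data.shape
    if x.data.shape[1] != C:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[1]} channels (axis 1), "
            f"kernel expects {C} (axis 1)")
    if padding == "same":
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("'same' padding requires odd kernel dims")
        ph, pw = kh // 2, kw // 2
    elif padding == "valid":
        ph = pw = 0
    else:
        raise ValueError(f"unknown padding mode {padding!r}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if ph or pw else x.data
    B, _, Hp, Wp = xp.shape
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    # strided windows (a view, no copy): [B, C, OH, OW, kh, kw]
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    out = np.tensordot(win, w.data, axes=([1, 4, 5], [1, 2, 3]))  # [B,OH,OW,O]
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if b is not None:
        b = _as_tensor(b)
        out += b.data.reshape(1, O, 1, 1)

    def bw(g):
        if w.requires_grad or w._parents:
            gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))
            w._accumulate(gw)
        if b is not None and (b.requires_grad or b._parents):
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gxp = np.zeros((B, C, Hp, Wp))
            for i in range(kh):  # scatter the adjoint of the window gather
                for j in range(kw):
                    gij = np.tensordot(g, w.data[:, :, i, j], axes=([1], [0]))
                    gxp[:, :, i:i + stride * OH:stride,
                        j:j + stride * OW:stride] += gij.transpose(0, 3, 1, 2)
            if ph or pw:
                gxp = gxp[:, :, ph:Hp - ph, pw:Wp - pw]
            x._accumulate(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, bw)


# -- pooling ---------------------------------------------------------------

def maxpool2d(x, window: int = 2, stride: Optional[int] = None) -> Tensor:
    x = _as_tensor(x)
    stride = window if stride is None else stride
    H, W = x.data.shape[-2:]
    if H % stride or W % stride:
        raise ValueError(
            f"maxpool2d: spatial dims ({H}, {W}) not divisible by stride {stride}")
    if (H - window) % stride or (W - window) % stride:
        raise ValueError(
            f"maxpool2d: window {window} with stride {stride} does not tile "
            f"({H}, {W})")
    win = sliding_window_view(x.data, (window, window),
                              axis=(-2, -1))[..., ::stride, ::stride, :, :]
    lead = win.shape[:-2]
    flat = win.reshape(lead + (window * window,))
    arg = flat.argmax(axis=-1)  # first occurrence on ties
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        OH, OW = out.shape[-2:]
        oi, oj = np.meshgrid(np.arange(OH), np.arange(OW), indexing="ij")
        di, dj = np.unravel_index(arg, (window, window))
        ri = oi * stride + di
        rj = oj * stride + dj
        flat_lead = int(np.prod(x.data.shape[:-2], dtype=int))
        gx2 = np.zeros((flat_lead, H, W))
        lead_idx = np.arange(flat_lead)[:, None, None]
        idx = (lead_idx, ri.reshape(flat_lead, OH, OW),
               rj.reshape(flat_lead, OH, OW))
        if stride >= window:  # non-overlapping windows: indices are unique
            gx2[idx] = g.reshape(flat_lead, OH, OW)
        else:
            np.add.at(gx2, idx, g.reshape(flat_lead, OH, OW))
        x._accumulate(gx2.reshape(x.data.shape))

    return _node(out, (x,), bw)


def avgpool2d(x, window: int = 2) -> Tensor:
    x = _as_tensor(x)
    H, W = x.data.shape[-2:]
    if H % window or W % window:
        raise ValueError(
            f"avgpool2d: spatial dims ({H}, {W}) not divisible by window {window}")
    lead = x.data.shape[:-2]
    out = x.data.reshape(lead + (H // window, window, W // window, window)).mean(
        axis=(-3, -1))

    def bw(g):
        gx = np.repeat(np.repeat(g, window, axis=-2), window, axis=-1)
        x._accumulate(gx / (window * window))

    return _node(out, (x,), bw)


# -- resampling ------------------------------------------------------------

_RESIZE_CACHE: dict[tuple, np.ndarray] = {}


def _resize_matrix(n_out: int, n_in: int, method: str) -> np.ndarray:
    """Row-stochastic 1-D interpolation matrix [n_out, n_in]."""
    key = (n_out, n_in, method)
    if key in _RESIZE_CACHE:
        return _RESIZE_CACHE[key]
    scale = n_in / n_out
    M = np.zeros((n_out, n_in))
    if method == "nearest":
        src = np.floor((np.arange(n_out) + 0.5) * scale).astype(int)
        src = np.clip(src, 0, n_in - 1)
        M[np.arange(n_out), src] = 1.0
    elif method == "bilinear":
        # half-pixel-centre convention (align_corners=False)
        src = (np.arange(n_out) + 0.5) * scale - 0.5
        lo = np.clip(np.floor(src).astype(int), 0, n_in - 1)
        hi = np.clip(lo + 1, 0, n_in - 1)
        frac = np.clip(src - np.floor(src), 0.0, 1.0)
        frac = np.where(hi == lo, 0.0, frac)
        M[np.arange(n_out), lo] += 1.0 - frac
        M[np.arange(n_out), hi] += frac
    else:
        raise ValueError(f"unknown resize method {method!r}")
    _RESIZE_CACHE[key] = M
    return M


def resize2d(x, out_h: int, out_w: int, method: str = "bilinear") -> Tensor:
    """Separable resampling of the trailing two axes (linear operator)."""
    x = _as_tensor(x)
    H, W = x.data.shape[-2:]
    Mh = _resize_matrix(out_h, H, method)
    Mw = _resize_matrix(out_w, W, method)
    out = np.einsum("oh,...hw,pw->...op", Mh, x.data, Mw, optimize=True)

    def bw(g):
        x._accumulate(np.einsum("oh,...op,pw->...hw", Mh, g, Mw, optimize=True))

    return _node(out, (x,), bw)


def upsample2d(x, factor: int, method: str = "bilinear") -> Tensor:
    x = _as_tensor(x)
    H, W = x.data.shape[-2:]
    return resize2d(x, H * factor, W * factor, method=method)


# -- Fourier ops -----------------------------------------------------------

def fft2_pair(xr, xi=None) -> tuple[Tensor, Tensor]:
    """Unnormalized forward 2-D DFT of paired real tensors.

    Returns (real, imag) of F = fft2(xr + i*xi).  The DFT is linear in the
    paired-real representation; the adjoint is N^2 times the inverse DFT.
    """
    xr = _as_tensor(xr)
    xi_t = _as_tensor(xi) if xi is not None else None
    z = xr.data if xi_t is None else xr.data + 1j * xi_t.data
    F = np.fft.fft2(z, axes=(-2, -1))
    fr_data, fi_data = F.real.copy(), F.imag.copy()
    H, W = xr.data.shape[-2:]
    parents = (xr,) if xi_t is None else (xr, xi_t)

    # Each output node applies the shared adjoint (N^2 * ifft2) to its own
    # incoming gradient; contributions accumulate on the inputs.
    def make_bw(is_real_output: bool):
        def bw(g):
            gz = g if is_real_output else 1j * g
            gc = np.fft.ifft2(gz, axes=(-2, -1)) * (H * W)
            xr._accumulate(gc.real)
            if xi_t is not None:
                xi_t._accumulate(gc.imag)
        return bw

    out_r = _node(fr_data, parents, make_bw(True))
    out_i = _node(fi_data, parents, make_bw(False))
    return out_r, out_i


def ifft2_real(fr, fi) -> Tensor:
    """Real part of the normalized (1/N^2) inverse 2-D DFT of fr + i*fi."""
    fr, fi = _as_tensor(fr), _as_tensor(fi)
    z = np.fft.ifft2(fr.data + 1j * fi.data, axes=(-2, -1))
    out = z.real.copy()

    def bw(g):
        gc = np.fft.ifft2(g, axes=(-2, -1))
        fr._accumulate(gc.real)
        fi._accumulate(-gc.imag)

    return _node(out, (fr, fi), bw)
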
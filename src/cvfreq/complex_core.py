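"""Complex-valued layer primitives.

A complex feature map I = I_re + i*I_im is stored as a pair of real tensors of
identical shape.  Every layer below acts on the pair with real-valued
operations only, following the split convention used throughout this family of
networks:

* complex convolution composes exactly four real convolutions,
  ``(I_re*K_re - I_im*K_im) + i(I_re*K_im + I_im*K_re)``;
* the split activations (CReLU, CSigmoid) and split max pooling apply their
  real counterpart to each part independently;
* complex upsampling interpolates each part with the same real resampler.

Because the pair representation is real, backpropagation through these layers
is ordinary real backpropagation on paired channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

ArrayLike = Union[np.ndarray, Tensor]


def _tensor(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


@dataclass
class ComplexFeatureMap:
    """Paired real/imaginary feature arrays of identical shape.

    The spatial layout is ``[..., channels, height, width]`` with an optional
    leading batch axis.
    """

    real_t: Tensor
    imag_t: Tensor

    def __init__(self, real: ArrayLike, imag: Optional[ArrayLike] = None):
        self.real_t = _tensor(real)
        self.imag_t = _tensor(imag if imag is not None
                              else np.zeros_like(self.real_t.data))
        if self.real_t.shape != self.imag_t.shape:
            raise ValueError(
                f"real/imag shape mismatch: {self.real_t.shape} vs {self.imag_t.shape}")

    @property
    def real(self) -> np.ndarray:
        return self.real_t.data

    @property
    def imag(self) -> np.ndarray:
        return self.imag_t.data

    @property
    def shape(self):
        return self.real_t.shape

    def to_complex(self) -> np.ndarray:
        return self.real + 1j * self.imag

    @classmethod
    def from_complex(cls, z: np.ndarray) -> "ComplexFeatureMap":
        z = np.asarray(z)
        return cls(z.real.copy(), z.imag.copy())

    def assert_finite(self) -> "ComplexFeatureMap":
        if not (np.isfinite(self.real).all() and np.isfinite(self.imag).all()):
            raise FloatingPointError("non-finite values in complex feature map")
        return self


@dataclass
class ComplexKernelSet:
    """Paired real/imaginary convolution weight banks with complex bias."""

    real_t: Tensor
    imag_t: Tensor
    bias_real_t: Optional[Tensor]
    bias_imag_t: Optional[Tensor]

    def __init__(self, real: ArrayLike, imag: ArrayLike,
                 bias_real: Optional[ArrayLike] = None,
                 bias_imag: Optional[ArrayLike] = None):
        self.real_t = _tensor(real)
        self.imag_t = _tensor(imag)
        if self.real_t.shape != self.imag_t.shape:
            raise ValueError(
                f"kernel real/imag shape mismatch: {self.real_t.shape} vs "
                f"{self.imag_t.shape}")
        if self.real_t.ndim != 4:
            raise ValueError("kernels must be [out_ch, in_ch, kh, kw]")
        kh, kw = self.real_t.shape[2:]
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError(f"kernel dims must be odd, got ({kh}, {kw})")
        self.bias_real_t = _tensor(bias_real) if bias_real is not None else None
        self.bias_imag_t = _tensor(bias_imag) if bias_imag is not None else None

    @property
    def real(self) -> np.ndarray:
        return self.real_t.data

    @property
    def imag(self) -> np.ndarray:
        return self.imag_t.data


def _batched(t: Tensor) -> tuple[Tensor, bool]:
    """Promote [C,H,W] to [1,C,H,W]; report whether a batch axis was added."""
    if t.ndim == 3:
        return ad.reshape(t, (1,) + t.shape), True
    return t, False


_reshape = ad.reshape


def cconv2d(inp: ComplexFeatureMap, kernel: ComplexKernelSet,
            stride: int = 1, padding: str = "same") -> ComplexFeatureMap:
    """Complex 2-D convolution built from four real convolutions.

    output_real = I_re * K_re - I_im * K_im + bias_real
    output_imag = I_re * K_im + I_im * K_re + bias_imag
    """
    xr, added = _batched(inp.real_t)
    xi, _ = _batched(inp.imag_t)
    in_ch = xr.shape[1]
    if in_ch != kernel.real_t.shape[1]:
        raise ValueError(
            f"channel mismatch: input channel axis has {in_ch}, kernel in_ch axis "
            f"has {kernel.real_t.shape[1]}")
    # Matrix form of the four real convolutions: one real convolution of the
    # stacked input [xr; xi] with the block kernel [[Kr, -Ki], [Ki, Kr]].
    out_ch = kernel.real_t.shape[0]
    xs = ad.concat([xr, xi], axis=1)
    top = ad.concat([kernel.real_t, ad.mul(kernel.imag_t, -1.0)], axis=1)
    bottom = ad.concat([kernel.imag_t, kernel.real_t], axis=1)
    wb = ad.concat([top, bottom], axis=0)
    bias = None
    if kernel.bias_real_t is not None or kernel.bias_imag_t is not None:
        br = kernel.bias_real_t if kernel.bias_real_t is not None else \
            ad.Tensor(np.zeros(out_ch))
        bi = kernel.bias_imag_t if kernel.bias_imag_t is not None else \
            ad.Tensor(np.zeros(out_ch))
        bias = ad.concat([br, bi], axis=0)
    y = ad.conv2d(xs, wb, bias, stride=stride, padding=padding)
    out_r = ad.crop_axis1(y, 0, out_ch)
    out_i = ad.crop_axis1(y, out_ch, out_ch)
    if added:
        out_r = _reshape(out_r, out_r.shape[1:])
        out_i = _reshape(out_i, out_i.shape[1:])
    return ComplexFeatureMap(out_r, out_i)


def crelu(inp: ComplexFeatureMap) -> ComplexFeatureMap:
    """Split ReLU: ReLU applied independently to real and imaginary parts."""
    return ComplexFeatureMap(ad.relu(inp.real_t), ad.relu(inp.imag_t))


def csigmoid(inp: ComplexFeatureMap) -> ComplexFeatureMap:
    """Split sigmoid: logistic function applied to each part independently.

    Both output parts lie in (0, 1).
    """
    return ComplexFeatureMap(ad.sigmoid(inp.real_t), ad.sigmoid(inp.imag_t))


def cmaxpool(inp: ComplexFeatureMap, window: int = 2,
             stride: Optional[int] = None,
             by_magnitude: bool = False) -> ComplexFeatureMap:
    """Split max pooling over each part independently.

    The pooled real and imaginary values within one window may originate from
    different pixels.  ``by_magnitude=True`` switches to a variant that picks,
    per window, the single complex value of largest magnitude (kept for
    comparison; the split form is the default).
    """
    stride = window if stride is None else stride
    if not by_magnitude:
        return ComplexFeatureMap(ad.maxpool2d(inp.real_t, window, stride),
                                 ad.maxpool2d(inp.imag_t, window, stride))
    # magnitude pooling: gather both parts at the argmax of |z|^2
    mag = ad.square(inp.real_t) + ad.square(inp.imag_t)
    H, W = mag.shape[-2:]
    if H % stride or W % stride:
        raise ValueError(
            f"cmaxpool: spatial dims ({H}, {W}) not divisible by stride {stride}")
    from numpy.lib.stride_tricks import sliding_window_view
    win = sliding_window_view(mag.data, (window, window),
                              axis=(-2, -1))[..., ::stride, ::stride, :, :]
    lead = win.shape[:-2]
    arg = win.reshape(lead + (window * window,)).argmax(axis=-1)
    di, dj = np.unravel_index(arg, (window, window))
    OH, OW = lead[-2:]
    oi, oj = np.meshgrid(np.arange(OH), np.arange(OW), indexing="ij")
    ri, rj = oi * stride + di, oj * stride + dj

    def gather(t: Tensor) -> Tensor:
        flat_lead = int(np.prod(t.data.shape[:-2], dtype=int))
        src = t.data.reshape(flat_lead, H, W)
        r2 = ri.reshape(flat_lead, OH, OW)
        c2 = rj.reshape(flat_lead, OH, OW)
        out = np.stack([src[k][r2[k], c2[k]] for k in range(flat_lead)])
        out = out.reshape(t.data.shape[:-2] + (OH, OW))

        def bw(g):
            gx = np.zeros_like(t.data).reshape(flat_lead, H, W)
            g2 = g.reshape(flat_lead, OH, OW)
            for k in range(flat_lead):
                np.add.at(gx[k], (r2[k], c2[k]), g2[k])
            t._accumulate(gx.reshape(t.data.shape))

        return ad._node(out, (t,), bw)

    return ComplexFeatureMap(gather(inp.real_t), gather(inp.imag_t))


def cupsample(inp: ComplexFeatureMap, factor: int = 2,
              method: str = "bilinear") -> ComplexFeatureMap:
    """Complex upsampling: the same real interpolation on each part."""
    if factor < 2:
        raise ValueError("upsampling factor must be >= 2")
    return ComplexFeatureMap(ad.upsample2d(inp.real_t, factor, method),
                             ad.upsample2d(inp.imag_t, factor, method))


def glorot_variance(shape: tuple[int, int, int, int]) -> float:
    out_ch, in_ch, kh, kw = shape
    fan_in = in_ch * kh * kw
    fan_out = out_ch * kh * kw
    return 2.0 / (fan_in + fan_out)


def init_complex_weights(shape: tuple[int, int, int, int], seed: int,
                         bias: bool = True,
                         trainable: bool = True) -> ComplexKernelSet:
    """Glorot-scaled complex initialization.

    Real and imaginary parts are drawn independently with per-part variance
    equal to half the Glorot variance, so the variance of the squared complex
    magnitude matches the Glorot variance of an equivalent real layer.
    Deterministic given the seed.  Biases start at zero.
    """
    rng = np.random.default_rng(seed)
    std = np.sqrt(glorot_variance(shape) / 2.0)
    wr = Tensor(rng.normal(0.0, std, size=shape), requires_grad=trainable)
    wi = Tensor(rng.normal(0.0, std, size=shape), requires_grad=trainable)
    out_ch = shape[0]
    br = bi = None
    if bias:
        br = Tensor(np.zeros(out_ch), requires_grad=trainable)
        bi = Tensor(np.zeros(out_ch), requires_grad=trainable)
    return ComplexKernelSet(wr, wi, br, bi)


def init_real_weights(shape: tuple[int, int, int, int], seed: int,
                      bias: bool = True, trainable: bool = True
                      ) -> tuple[Tensor, Optional[Tensor]]:
    """Glorot-normal initialization for a real convolution layer."""
    rng = np.random.default_rng(seed)
    std = np.sqrt(glorot_variance(shape))
    w = Tensor(rng.normal(0.0, std, size=shape), requires_grad=trainable)
    b = Tensor(np.zeros(shape[0]), requires_grad=trainable) if bias else None
    return w, b


def cmul(a: ComplexFeatureMap, b: ComplexFeatureMap) -> ComplexFeatureMap:
    """Element-wise complex product (a_re*b_re - a_im*b_im, a_re*b_im + a_im*b_re)."""
    out_r = a.real_t * b.real_t - a.imag_t * b.imag_t
    out_i = a.real_t * b.imag_t + a.imag_t * b.real_t
    return ComplexFeatureMap(out_r, out_i)


def cadd(a: ComplexFeatureMap, b: ComplexFeatureMap) -> ComplexFeatureMap:
    return ComplexFeatureMap(a.real_t + b.real_t, a.imag_t + b.imag_t)


def cconcat(maps: list[ComplexFeatureMap], axis: int = -3) -> ComplexFeatureMap:
    """Concatenate complex maps along the channel axis."""
    ndim = maps[0].real_t.ndim
    ax = axis % ndim
    return ComplexFeatureMap(ad.concat([m.real_t for m in maps], axis=ax),
                             ad.concat([m.imag_t for m in maps], axis=ax))
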
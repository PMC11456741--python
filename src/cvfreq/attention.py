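"""Attention gates for skip connections, real-valued and complex-valued.

The real gate is the additive soft-attention gate of the Attention-UNet
lineage: features x (fine scale) and a gating signal g (coarser scale) are
projected by 1x1 channel-wise convolutions to a shared intermediate width,
summed, passed through ReLU, a 1x1 convolution with bias, and a sigmoid; the
resulting weights beta in [0, 1] are interpolated back to the feature
resolution and multiply the features element-wise.

The complex gate rebuilds the same chain from complex primitives (complex 1x1
convolutions, split ReLU, split sigmoid, complex upsampling), producing
complex weights alpha whose parts lie in (0, 1).  The gated output combines
features and weights by a per-pixel complex product — the complex cross-term
rule applied pointwise, the natural complex generalization of the real gate's
element-wise product.  A full-map "valid" convolution combine is available as
an ablation flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .complex_core import (ComplexFeatureMap, cadd, cmul, crelu, csigmoid,
                           cupsample)
from .modules import ComplexConv2d, Module, RealConv2d


@dataclass
class AttentionContext:
    """Input features plus coarser-scale gating signal (both real or both complex)."""

    features: Union[np.ndarray, Tensor, ComplexFeatureMap]
    gating: Union[np.ndarray, Tensor, ComplexFeatureMap]
    intermediate_channels: Optional[int] = None

    def is_complex(self) -> bool:
        return isinstance(self.features, ComplexFeatureMap)


def _as4d(x) -> tuple[Tensor, bool]:
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
    if t.ndim == 3:
        return ad.reshape(t, (1,) + t.shape), True
    return t, False


def _pool_to(x: Tensor, target_hw: tuple[int, int]) -> Tensor:
    """Strided average pooling down to the gating resolution."""
    H, W = x.shape[-2:]
    th, tw = target_hw
    if (H, W) == (th, tw):
        return x
    if H % th or W % tw or H // th != W // tw:
        raise ValueError(
            f"feature dims ({H}, {W}) not an integer multiple of gating dims "
            f"({th}, {tw})")
    return ad.avgpool2d(x, H // th)


class RealAttentionGate(Module):
    """beta = sigmoid(W_s(ReLU(W_x x + W_g g + b_g)) + b_s); output = x * beta."""

    def __init__(self, feature_ch: int, gating_ch: int,
                 intermediate_ch: Optional[int] = None, seed: int = 0,
                 upsample_method: str = "bilinear"):
        inter = intermediate_ch or max(1, feature_ch // 2)
        self.wx = RealConv2d(feature_ch, inter, kernel=1, seed=seed, bias=False)
        self.wg = RealConv2d(gating_ch, inter, kernel=1, seed=seed + 1, bias=True)
        # small positive combining bias keeps the gate's ReLU initially active
        self.wg.b.data[:] = 0.1
        self.ws = RealConv2d(inter, 1, kernel=1, seed=seed + 2, bias=True)
        self.upsample_method = upsample_method

    def weights(self, features: Tensor, gating: Tensor) -> Tensor:
        """Attention weights beta at the feature resolution, values in [0, 1]."""
        gh, gw = gating.shape[-2:]
        xd = _pool_to(features, (gh, gw))
        s = ad.relu(self.wx(xd) + self.wg(gating))
        beta = ad.sigmoid(self.ws(s))
        fh, fw = features.shape[-2:]
        return ad.resize2d(beta, fh, fw, method=self.upsample_method)

    def __call__(self, features: Tensor, gating: Tensor) -> Tensor:
        return features * self.weights(features, gating)


class ComplexAttentionGate(Module):
    """The real gate chain rebuilt from complex primitives (CReLU, CSigmoid)."""

    def __init__(self, feature_ch: int, gating_ch: int,
                 intermediate_ch: Optional[int] = None, seed: int = 0,
                 upsample_method: str = "bilinear",
                 combine: str = "pixelwise"):
        inter = intermediate_ch or max(1, feature_ch // 2)
        self.wx = ComplexConv2d(feature_ch, inter, kernel=1, seed=seed, bias=False)
        self.wg = ComplexConv2d(gating_ch, inter, kernel=1, seed=seed + 1, bias=True)
        # small positive combining bias keeps both split ReLUs initially active
        self.wg.kernel_set.bias_real_t.data[:] = 0.1
        self.wg.kernel_set.bias_imag_t.data[:] = 0.1
        self.ws = ComplexConv2d(inter, 1, kernel=1, seed=seed + 2, bias=True)
        self.upsample_method = upsample_method
        if combine not in ("pixelwise", "conv"):
            raise ValueError(f"unknown combine mode {combine!r}")
        self.combine = combine

    def weights(self, features: ComplexFeatureMap,
                gating: ComplexFeatureMap) -> ComplexFeatureMap:
        """Complex attention weights alpha, both parts in (0, 1)."""
        gh, gw = gating.shape[-2:]
        xd = ComplexFeatureMap(_pool_to(features.real_t, (gh, gw)),
                               _pool_to(features.imag_t, (gh, gw)))
        s = crelu(cadd(self.wx(xd), self.wg(gating)))
        alpha = csigmoid(self.ws(s))
        fh, fw = features.shape[-2:]
        factor = fh // gh
        if factor > 1:
            alpha = cupsample(alpha, factor, method=self.upsample_method)
        return alpha

    def __call__(self, features: ComplexFeatureMap,
                 gating: ComplexFeatureMap) -> ComplexFeatureMap:
        alpha = self.weights(features, gating)
        if self.combine == "pixelwise":
            return cmul(features, alpha)
        # ablation: zero-lag full-map correlation per channel (a "valid"
        # whole-image convolution support); collapses spatial dims to 1x1
        prod = cmul(features, alpha)
        lead = prod.shape[:-2]
        r = ad.reshape(prod.real_t, lead + (-1,))
        i = ad.reshape(prod.imag_t, lead + (-1,))
        return ComplexFeatureMap(_sum_last(r), _sum_last(i))


def _sum_last(t: Tensor) -> Tensor:
    data = t.data.sum(axis=-1, keepdims=True)

    def bw(g):
        t._accumulate(np.broadcast_to(g, t.data.shape))

    out = ad._node(data, (t,), bw)
    return ad.reshape(out, t.shape[:-1] + (1, 1))


def real_attention_gate(ctx: AttentionContext,
                        gate: Optional[RealAttentionGate] = None,
                        seed: int = 0) -> Tensor:
    """Apply a real attention gate to an :class:`AttentionContext`.

    A gate module is created (seeded) if none is supplied.
    """
    if ctx.is_complex():
        raise TypeError("context is complex-valued; use complex_attention_gate")
    x, added = _as4d(ctx.features)
    g, _ = _as4d(ctx.gating)
    if gate is None:
        gate = RealAttentionGate(x.shape[1], g.shape[1],
                                 ctx.intermediate_channels, seed=seed)
    out = gate(x, g)
    return ad.reshape(out, out.shape[1:]) if added else out


def complex_attention_gate(ctx: AttentionContext,
                           gate: Optional[ComplexAttentionGate] = None,
                           seed: int = 0) -> ComplexFeatureMap:
    """Apply a complex attention gate to an :class:`AttentionContext`."""
    if not ctx.is_complex():
        raise TypeError("context is real-valued; use real_attention_gate")
    feats: ComplexFeatureMap = ctx.features
    gat: ComplexFeatureMap = ctx.gating
    xr, added = _as4d(feats.real_t)
    xi, _ = _as4d(feats.imag_t)
    gr, _ = _as4d(gat.real_t)
    gi, _ = _as4d(gat.imag_t)
    x4 = ComplexFeatureMap(xr, xi)
    g4 = ComplexFeatureMap(gr, gi)
    if gate is None:
        gate = ComplexAttentionGate(xr.shape[1], gr.shape[1],
                                    ctx.intermediate_channels, seed=seed)
    out = gate(x4, g4)
    if added:
        out = ComplexFeatureMap(ad.reshape(out.real_t, out.shape[1:]),
                                ad.reshape(out.imag_t, out.shape[1:]))
    return out
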
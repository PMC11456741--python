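"""Restoration architectures assembled from the complex and real primitives.

Six networks are provided:

* ``cv_atten_unet`` — a fully complex attention U-Net operating on the centred
  Fourier representation of the input: FTE, n complex encoder blocks
  (CV-Conv, CReLU, CV-Conv, CReLU, CMax-pool), n complex decoder blocks
  (CV-Conv, CReLU, CV-Conv, CReLU, CUpsample), complex attention gates on each
  skip connection, and a final block of FTD merged with one real convolution.
* ``cv_can`` — a serial spatial/frequency scheme: real encoder blocks, FTE,
  complex encoder/decoder blocks, FTD, real decoder blocks, with real gates on
  the real skips and complex gates on the complex skips.
* ``cv_ddan`` — a dual-domain parallel scheme: a real-gated spatial branch and
  a complex-gated frequency branch on the same source image, fused additively
  and passed through a final output convolution.
* ``cv_srn`` — the complex attention U-Net body on a half-size input, decoded
  by FTD and followed by an upsampling block (x2 interpolation + convolution),
  doubling the spatial dimensions (e.g. 512x512 in, 1024x1024 out).
* ``unet`` and ``attention_unet`` — real-valued baselines with the same block
  layout (skips ungated / gated by real attention gates).

Skip fusion follows the Attention-UNet lineage: the gate's gating signal is
the decoder's pre-upsampling (coarser-scale) output, the gated skip is
concatenated with the upsampled decoder features at the next block's input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .attention import ComplexAttentionGate, RealAttentionGate
from .complex_core import (ComplexFeatureMap, cconcat, cmaxpool, crelu,
                           cupsample)
from .fourier import fte, ftd
from .modules import ComplexConv2d, Module, RealConv2d

ARCH_NAMES = ("cv_atten_unet", "cv_can", "cv_ddan", "cv_srn", "unet",
              "attention_unet")

_DEFAULT_BLOCKS = {"cv_atten_unet": 4, "cv_ddan": 4, "cv_srn": 4,
                   "cv_can": 2, "unet": 4, "attention_unet": 4}


@dataclass
class ArchitectureConfig:
    """Block counts, channel widths, kernel size and seed for one network."""

    name: str
    n_blocks: Optional[int] = None
    base_channels: int = 32
    growth: int = 2
    kernel: int = 3
    seed: int = 0
    upsample_method: str = "bilinear"
    in_channels: int = 1

    def __post_init__(self):
        if self.name not in ARCH_NAMES:
            raise ValueError(f"unknown architecture {self.name!r}; "
                             f"choose from {ARCH_NAMES}")
        if self.n_blocks is None:
            self.n_blocks = _DEFAULT_BLOCKS[self.name]

    @property
    def divisor(self) -> int:
        """Required divisibility of the input spatial dims."""
        if self.name == "cv_can":
            return 2 ** (2 * self.n_blocks)
        return 2 ** self.n_blocks

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        return cls(**d)


class _SeedStream:
    def __init__(self, seed: int):
        self._rng = np.random.default_rng(seed)

    def __call__(self) -> int:
        return int(self._rng.integers(0, 2 ** 31 - 1))


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class RealEncoderBlock(Module):
    """Conv -> ReLU -> Conv -> ReLU -> MaxPool; returns (skip, pooled)."""

    def __init__(self, in_ch, out_ch, kernel, seeds):
        self.c1 = RealConv2d(in_ch, out_ch, kernel, seed=seeds())
        self.c2 = RealConv2d(out_ch, out_ch, kernel, seed=seeds())

    def __call__(self, x):
        skip = ad.relu(self.c2(ad.relu(self.c1(x))))
        return skip, ad.maxpool2d(skip, 2)


class RealDecoderBlock(Module):
    """Conv -> ReLU -> Conv -> ReLU -> Upsample; returns (pre_up, upsampled)."""

    def __init__(self, in_ch, out_ch, kernel, seeds, method):
        self.c1 = RealConv2d(in_ch, out_ch, kernel, seed=seeds())
        self.c2 = RealConv2d(out_ch, out_ch, kernel, seed=seeds())
        self.method = method

    def __call__(self, x):
        pre = ad.relu(self.c2(ad.relu(self.c1(x))))
        return pre, ad.upsample2d(pre, 2, method=self.method)


class ComplexEncoderBlock(Module):
    """CV-Conv -> CReLU -> CV-Conv -> CReLU -> CMax-pool."""

    def __init__(self, in_ch, out_ch, kernel, seeds):
        self.c1 = ComplexConv2d(in_ch, out_ch, kernel, seed=seeds())
        self.c2 = ComplexConv2d(out_ch, out_ch, kernel, seed=seeds())

    def __call__(self, x):
        skip = crelu(self.c2(crelu(self.c1(x))))
        return skip, cmaxpool(skip, 2)


class ComplexDecoderBlock(Module):
    """CV-Conv -> CReLU -> CV-Conv -> CReLU -> CUpsample."""

    def __init__(self, in_ch, out_ch, kernel, seeds, method):
        self.c1 = ComplexConv2d(in_ch, out_ch, kernel, seed=seeds())
        self.c2 = ComplexConv2d(out_ch, out_ch, kernel, seed=seeds())
        self.method = method

    def __call__(self, x):
        pre = crelu(self.c2(crelu(self.c1(x))))
        return pre, cupsample(pre, 2, method=self.method)


# ---------------------------------------------------------------------------
# encoder/decoder bodies
# ---------------------------------------------------------------------------

class ComplexUNetBody(Module):
    """n complex encoder + n complex decoder blocks with complex gates.

    Input: complex map with `in_ch` channels; output: complex map with
    ``2*base`` channels at the input resolution.
    """

    def __init__(self, in_ch, n, base, growth, kernel, seeds, method):
        cs = [base * growth ** i for i in range(n)]
        self.encoders = [ComplexEncoderBlock(in_ch if i == 0 else cs[i - 1],
                                             cs[i], kernel, seeds)
                         for i in range(n)]
        self.decoders = [ComplexDecoderBlock(
            cs[n - 1] if k == 0 else 2 * cs[n - k],
            cs[n - 1 - k], kernel, seeds, method) for k in range(n)]
        self.gates = [ComplexAttentionGate(cs[n - 1 - k], cs[n - 1 - k],
                                           seed=seeds(), upsample_method=method)
                      for k in range(n)]
        self.out_channels = 2 * cs[0]

    def __call__(self, x: ComplexFeatureMap) -> ComplexFeatureMap:
        skips = []
        h = x
        for enc in self.encoders:
            skip, h = enc(h)
            skips.append(skip)
        up = None
        for k, dec in enumerate(self.decoders):
            inp = h if k == 0 else cconcat(
                [up, self.gates[k - 1](skips[-k], pre)], axis=1)
            pre, up = dec(inp)
        gated = self.gates[-1](skips[0], pre)
        return cconcat([up, gated], axis=1)


class RealUNetBody(Module):
    """Real twin of :class:`ComplexUNetBody`; skips gated or plain."""

    def __init__(self, in_ch, n, base, growth, kernel, seeds, method,
                 gated: bool):
        cs = [base * growth ** i for i in range(n)]
        self.encoders = [RealEncoderBlock(in_ch if i == 0 else cs[i - 1],
                                          cs[i], kernel, seeds)
                         for i in range(n)]
        self.decoders = [RealDecoderBlock(
            cs[n - 1] if k == 0 else 2 * cs[n - k],
            cs[n - 1 - k], kernel, seeds, method) for k in range(n)]
        self.gated = gated
        if gated:
            self.gates = [RealAttentionGate(cs[n - 1 - k], cs[n - 1 - k],
                                            seed=seeds(), upsample_method=method)
                          for k in range(n)]
        else:
            # consume the same number of seeds so weight layouts stay aligned
            self.gates = []
        self.out_channels = 2 * cs[0]

    def _gate(self, k, skip, g):
        return self.gates[k](skip, g) if self.gated else skip

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        h = x
        for enc in self.encoders:
            skip, h = enc(h)
            skips.append(skip)
        up = None
        for k, dec in enumerate(self.decoders):
            inp = h if k == 0 else ad.concat(
                [up, self._gate(k - 1, skips[-k], pre)], axis=1)
            pre, up = dec(inp)
        gated = self._gate(len(self.decoders) - 1, skips[0], pre)
        return ad.concat([up, gated], axis=1)


# ---------------------------------------------------------------------------
# full networks
# ---------------------------------------------------------------------------

def _check_dims(h: int, w: int, divisor: int, name: str):
    if h % divisor or w % divisor:
        raise ValueError(
            f"{name}: input spatial dims ({h}, {w}) must be divisible by "
            f"{divisor}")


def _as_batched_real(image) -> tuple[Tensor, int]:
    """Return [B, C, H, W] tensor and the number of axes that were added."""
    t = image if isinstance(image, Tensor) else Tensor(np.asarray(image, float))
    added = 4 - t.ndim
    if added < 0 or added > 2:
        raise ValueError(f"expected 2-D to 4-D input, got shape {t.shape}")
    for _ in range(added):
        t = ad.reshape(t, (1,) + t.shape)
    return t, added


def _squeeze(t: Tensor, added: int) -> Tensor:
    for _ in range(added):
        t = ad.reshape(t, t.shape[1:])
    return t


class CVAttenUNet(Module):
    def __init__(self, config: ArchitectureConfig):
        self.config = config
        seeds = _SeedStream(config.seed)
        self.body = ComplexUNetBody(config.in_channels, config.n_blocks,
                                    config.base_channels, config.growth,
                                    config.kernel, seeds,
                                    config.upsample_method)
        self.final = RealConv2d(self.body.out_channels, 1, config.kernel,
                                seed=seeds())

    def __call__(self, image):
        x, added = _as_batched_real(image)
        _check_dims(*x.shape[-2:], self.config.divisor, self.config.name)
        z = fte(x)
        z = self.body(z)
        spatial = ftd(z)
        return _squeeze(self.final(spatial), added)


class CVCAN(Module):
    """Serial scheme: real encoders, FTE, complex blocks, FTD, real decoders."""

    def __init__(self, config: ArchitectureConfig):
        self.config = config
        n, base, g, k = (config.n_blocks, config.base_channels, config.growth,
                         config.kernel)
        seeds = _SeedStream(config.seed)
        method = config.upsample_method
        rcs = [base * g ** i for i in range(n)]
        ccs = [base * g ** (n + i) for i in range(n)]
        self.rencoders = [RealEncoderBlock(config.in_channels if i == 0
                                           else rcs[i - 1], rcs[i], k, seeds)
                          for i in range(n)]
        self.cencoders = [ComplexEncoderBlock(rcs[-1] if i == 0 else ccs[i - 1],
                                              ccs[i], k, seeds)
                          for i in range(n)]
        self.cdecoders = [ComplexDecoderBlock(
            ccs[n - 1] if j == 0 else 2 * ccs[n - j],
            ccs[n - 1 - j], k, seeds, method) for j in range(n)]
        self.cgates = [ComplexAttentionGate(ccs[n - 1 - j], ccs[n - 1 - j],
                                            seed=seeds(), upsample_method=method)
                       for j in range(n)]
        self.rdecoders = [RealDecoderBlock(
            2 * ccs[0] if j == 0 else 2 * rcs[n - j],
            rcs[n - 1 - j], k, seeds, method) for j in range(n)]
        self.rgates = [RealAttentionGate(rcs[n - 1 - j], rcs[n - 1 - j],
                                         seed=seeds(), upsample_method=method)
                       for j in range(n)]
        self.final = RealConv2d(2 * rcs[0], 1, k, seed=seeds())

    def __call__(self, image):
        x, added = _as_batched_real(image)
        _check_dims(*x.shape[-2:], self.config.divisor, self.config.name)
        rskips = []
        h = x
        for enc in self.rencoders:
            skip, h = enc(h)
            rskips.append(skip)
        z = fte(h)  # channel-wise transform of the pooled real features
        cskips = []
        for enc in self.cencoders:
            skip, z = enc(z)
            cskips.append(skip)
        up = None
        for j, dec in enumerate(self.cdecoders):
            inp = z if j == 0 else cconcat(
                [up, self.cgates[j - 1](cskips[-j], pre)], axis=1)
            pre, up = dec(inp)
        z = cconcat([up, self.cgates[-1](cskips[0], pre)], axis=1)
        h = ftd(z)
        rpre = None
        for j, dec in enumerate(self.rdecoders):
            inp = h if j == 0 else ad.concat(
                [rup, self.rgates[j - 1](rskips[-j], rpre)], axis=1)
            rpre, rup = dec(inp)
        h = ad.concat([rup, self.rgates[-1](rskips[0], rpre)], axis=1)
        return _squeeze(self.final(h), added)


class CVDDAN(Module):
    """Parallel dual-domain scheme with additive fusion of the two branches."""

    def __init__(self, config: ArchitectureConfig):
        self.config = config
        seeds = _SeedStream(config.seed)
        n, base, g, k = (config.n_blocks, config.base_channels, config.growth,
                         config.kernel)
        method = config.upsample_method
        self.spatial_body = RealUNetBody(config.in_channels, n, base, g, k,
                                         seeds, method, gated=True)
        self.spatial_out = RealConv2d(self.spatial_body.out_channels, 1, k,
                                      seed=seeds())
        self.complex_body = ComplexUNetBody(config.in_channels, n, base, g, k,
                                            seeds, method)
        self.complex_out = RealConv2d(self.complex_body.out_channels, 1, k,
                                      seed=seeds())
        self.final = RealConv2d(1, 1, k, seed=seeds())

    def __call__(self, image):
        x, added = _as_batched_real(image)
        _check_dims(*x.shape[-2:], self.config.divisor, self.config.name)
        spatial = self.spatial_out(self.spatial_body(x))
        z = fte(x)
        freq = self.complex_out(ftd(self.complex_body(z)))
        return _squeeze(self.final(spatial + freq), added)


class CVSRN(Module):
    """Super-resolution: complex attention U-Net body + x2 upsampling block."""

    def __init__(self, config: ArchitectureConfig):
        self.config = config
        seeds = _SeedStream(config.seed)
        self.body = ComplexUNetBody(config.in_channels, config.n_blocks,
                                    config.base_channels, config.growth,
                                    config.kernel, seeds,
                                    config.upsample_method)
        self.final = RealConv2d(self.body.out_channels, 1, config.kernel,
                                seed=seeds())

    def __call__(self, image_lr):
        if isinstance(image_lr, ComplexFeatureMap):
            h, w = image_lr.shape[-2:]
            if h != w:
                raise ValueError(f"cv_srn requires square input, got ({h}, {w})")
            _check_dims(h, w, self.config.divisor, self.config.name)
            z = image_lr
            added = 0
            if z.real_t.ndim == 3:
                z = ComplexFeatureMap(ad.reshape(z.real_t, (1,) + z.shape),
                                      ad.reshape(z.imag_t, (1,) + z.shape))
                added = 1
            elif z.real_t.ndim == 2:
                z = ComplexFeatureMap(ad.reshape(z.real_t, (1, 1) + z.shape),
                                      ad.reshape(z.imag_t, (1, 1) + z.shape))
                added = 2
        else:
            x, added = _as_batched_real(image_lr)
            h, w = x.shape[-2:]
            if h != w:
                raise ValueError(f"cv_srn requires square input, got ({h}, {w})")
            _check_dims(h, w, self.config.divisor, self.config.name)
            z = fte(x)
        z = self.body(z)
        spatial = ftd(z)
        up = ad.upsample2d(spatial, 2, method=self.config.upsample_method)
        return _squeeze(self.final(up), added)


class UNet(Module):
    def __init__(self, config: ArchitectureConfig, gated: bool = False):
        self.config = config
        seeds = _SeedStream(config.seed)
        self.body = RealUNetBody(config.in_channels, config.n_blocks,
                                 config.base_channels, config.growth,
                                 config.kernel, seeds, config.upsample_method,
                                 gated=gated)
        self.final = RealConv2d(self.body.out_channels, 1, config.kernel,
                                seed=seeds())

    def __call__(self, image):
        x, added = _as_batched_real(image)
        _check_dims(*x.shape[-2:], self.config.divisor, self.config.name)
        return _squeeze(self.final(self.body(x)), added)


class AttentionUNet(UNet):
    def __init__(self, config: ArchitectureConfig):
        super().__init__(config, gated=True)


_BUILDERS = {
    "cv_atten_unet": CVAttenUNet,
    "cv_can": CVCAN,
    "cv_ddan": CVDDAN,
    "cv_srn": CVSRN,
    "unet": UNet,
    "attention_unet": AttentionUNet,
}


def build_model(config: ArchitectureConfig) -> Module:
    return _BUILDERS[config.name](config)


def count_parameters(config: ArchitectureConfig) -> int:
    """Trainable scalar parameter count (a complex weight counts as two)."""
    return build_model(config).n_parameters()


# functional surface ---------------------------------------------------------

def forward_cv_atten_unet(image, config: ArchitectureConfig) -> Tensor:
    return CVAttenUNet(config)(image)


def forward_cv_can(image, config: ArchitectureConfig) -> Tensor:
    return CVCAN(config)(image)


def forward_cv_ddan(image, config: ArchitectureConfig) -> Tensor:
    return CVDDAN(config)(image)


def forward_cv_srn(image_lr, config: ArchitectureConfig) -> Tensor:
    return CVSRN(config)(image_lr)


def forward_unet(image, config: ArchitectureConfig) -> Tensor:
    return UNet(config)(image)


def forward_attention_unet(image, config: ArchitectureConfig) -> Tensor:
    return AttentionUNet(config)(image)
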
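"""Lightweight module system: named parameters, real and complex conv layers."""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .complex_core import (ComplexFeatureMap, ComplexKernelSet, cconv2d,
                           init_complex_weights, init_real_weights)


class Module:
    """Base class: children and parameters discovered from instance attributes."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, ComplexKernelSet):
                for part in ("real_t", "imag_t", "bias_real_t", "bias_imag_t"):
                    t = getattr(value, part)
                    if isinstance(t, Tensor) and t.requires_grad:
                        yield f"{full}.{part}", t
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state mismatch: missing keys {sorted(missing)}, "
                f"unexpected keys {sorted(extra)}")
        for k, t in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: checkpoint {arr.shape} vs "
                    f"model {t.data.shape}")
            t.data = arr.copy()


class RealConv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, seed: int = 0,
                 bias: bool = True, padding: str = "same"):
        self.padding = padding
        self.w, self.b = init_real_weights((out_ch, in_ch, kernel, kernel),
                                           seed=seed, bias=bias)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b, padding=self.padding)


class ComplexConv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, seed: int = 0,
                 bias: bool = True, padding: str = "same"):
        self.padding = padding
        self.kernel_set = init_complex_weights((out_ch, in_ch, kernel, kernel),
                                               seed=seed, bias=bias)

    def __call__(self, x: ComplexFeatureMap) -> ComplexFeatureMap:
        return cconv2d(x, self.kernel_set, padding=self.padding)


class Adam:
    """ADAM optimizer with the conventional defaults."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
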
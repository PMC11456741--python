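"""Fourier transform encoding/decoding layers.

The encoding layer (FTE) maps a real spatial feature map to its complex
frequency representation with the DC coefficient moved to the centre pixel
(row ``H//2``, column ``W//2``).  The decoding layer (FTD) undoes the shift,
applies the normalized inverse DFT and returns the real part.

Conventions (per-channel 2-D transforms):

* forward DFT is unnormalized: ``F(u,v) = sum_pq I(p,q) exp(-2*pi*i(up/H + vq/W))``
* inverse DFT carries the full ``1/(H*W)`` factor

so ``ftd(fte(x)) == x`` exactly (up to float rounding) and Parseval reads
``sum |F|^2 = H*W * sum |I|^2``.  Both layers are linear, hence differentiable
end-to-end; they participate in backpropagation like any other layer.
"""

from __future__ import annotations

import logging

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .complex_core import ComplexFeatureMap

logger = logging.getLogger(__name__)


def dc_shift(spectrum: ComplexFeatureMap) -> ComplexFeatureMap:
    """Move the DC coefficient from (0, 0) to (H//2, W//2).

    Index map ``i -> (i + floor(n/2)) mod n`` on both trailing axes (the
    fftshift convention, exact for odd and even sizes); an involution only for
    even sizes, so use :func:`dc_unshift` to invert in general.
    """
    H, W = spectrum.shape[-2:]
    return ComplexFeatureMap(ad.roll2d(spectrum.real_t, H // 2, W // 2),
                             ad.roll2d(spectrum.imag_t, H // 2, W // 2))


def dc_unshift(spectrum: ComplexFeatureMap) -> ComplexFeatureMap:
    """Inverse of :func:`dc_shift`, exact for odd and even sizes."""
    H, W = spectrum.shape[-2:]
    return ComplexFeatureMap(ad.roll2d(spectrum.real_t, -(H // 2), -(W // 2)),
                             ad.roll2d(spectrum.imag_t, -(H // 2), -(W // 2)))


def fte(image) -> ComplexFeatureMap:
    """Fourier transform encoding: spatial -> centred complex spectrum.

    Accepts a real array/Tensor of shape [..., H, W] (channels transformed
    independently) or a :class:`ComplexFeatureMap` (already-complex features,
    as produced mid-network).
    """
    if isinstance(image, ComplexFeatureMap):
        fr, fi = ad.fft2_pair(image.real_t, image.imag_t)
    else:
        x = image if isinstance(image, Tensor) else Tensor(np.asarray(image, float))
        fr, fi = ad.fft2_pair(x)
    return dc_shift(ComplexFeatureMap(fr, fi))


def ftd(spectrum: ComplexFeatureMap, warn_tol: float = 1e-5) -> Tensor:
    """Fourier transform decoding: centred spectrum -> real spatial map.

    Applies the inverse shift, the 1/(H*W)-normalized inverse DFT, and returns
    the real part.  If the discarded imaginary residue exceeds ``warn_tol``
    times the norm of the real part, a diagnostic is logged (the residue is
    numerically tiny for spectra produced by the network from real inputs only
    when the network preserves Hermitian symmetry, which trained complex
    layers generally do not — the real part is the defined output either way).
    """
    un = dc_unshift(spectrum)
    z = np.fft.ifft2(un.real + 1j * un.imag, axes=(-2, -1))
    imag_norm = float(np.linalg.norm(z.imag))
    real_norm = float(np.linalg.norm(z.real))
    if imag_norm > warn_tol * max(real_norm, 1e-300):
        logger.info("ftd: discarded imaginary residue |im|/|re| = %.3e",
                    imag_norm / max(real_norm, 1e-300))
    return ad.ifft2_real(un.real_t, un.imag_t)


def spectrum_magnitude(spectrum: ComplexFeatureMap) -> np.ndarray:
    """|F| of a centred spectrum, for display/export."""
    return np.abs(spectrum.to_complex())
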
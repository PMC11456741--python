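"""Restoration quality metrics: PSNR, SSIM, and Fourier-spectrum preservation.

PSNR and SSIM are the standard measures; the radial spectrum profile and the
spectral distance quantify how well a restored image preserves the reference
image's frequency content — real-valued denoisers tend to suppress high
frequencies (spectral bias), and the frequency-domain models are designed to
avoid exactly that, so the high-frequency band of the radial profile is the
discriminating statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

PSNR_IDENTICAL = math.inf  # sentinel for zero-MSE pairs


def psnr(test: np.ndarray, reference: np.ndarray,
         max_value: float = 1.0) -> float:
    """Peak signal-to-noise ratio, ``10*log10(max_value^2 / MSE)`` in dB.

    Identical images return ``math.inf`` (the documented sentinel), never an
    exception.
    """
    test = np.asarray(test, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if test.shape != reference.shape:
        raise ValueError(f"shape mismatch: {test.shape} vs {reference.shape}")
    mse = float(np.mean((test - reference) ** 2))
    if mse == 0.0:
        return PSNR_IDENTICAL
    return 10.0 * math.log10(max_value ** 2 / mse)


def ssim(test: np.ndarray, reference: np.ndarray,
         max_value: float = 1.0, sigma: float = 1.5,
         k1: float = 0.01, k2: float = 0.03,
         truncate: float = 3.5) -> float:
    """Mean structural similarity with a Gaussian window (sigma 1.5).

    The Wang et al. formulation: local means, variances and covariance are
    estimated with an 11x11 Gaussian-weighted window (sigma=1.5, truncated at
    3.5 sigma), stabilized by C1=(k1*L)^2, C2=(k2*L)^2 with dynamic range L.
    """
    test = np.asarray(test, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if test.shape != reference.shape:
        raise ValueError(f"shape mismatch: {test.shape} vs {reference.shape}")
    win = 2 * int(truncate * sigma + 0.5) + 1  # 11 for sigma=1.5
    if min(test.shape[-2:]) < win:
        raise ValueError(
            f"images smaller than the {win}x{win} SSIM window: {test.shape}")
    c1 = (k1 * max_value) ** 2
    c2 = (k2 * max_value) ** 2

    def filt(a):
        return gaussian_filter(a, sigma=sigma, truncate=truncate, mode="reflect")

    mu_x = filt(test)
    mu_y = filt(reference)
    mu_xx = mu_x * mu_x
    mu_yy = mu_y * mu_y
    mu_xy = mu_x * mu_y
    # unbiased-style normalization matching the reference implementation
    cov_norm = 1.0  # Gaussian weights sum to 1; sample (not unbiased) moments
    var_x = filt(test * test) - mu_xx
    var_y = filt(reference * reference) - mu_yy
    cov = filt(test * reference) - mu_xy
    num = (2 * mu_xy + c1) * (2 * cov_norm * cov + c2)
    den = (mu_xx + mu_yy + c1) * (cov_norm * (var_x + var_y) + c2)
    s = num / den
    pad = (win - 1) // 2  # crop the filter's edge-effect margin
    interior = s[..., pad:s.shape[-2] - pad, pad:s.shape[-1] - pad]
    return float(interior.mean())


def radial_spectrum(image: np.ndarray, n_bins: int | None = None) -> np.ndarray:
    """Azimuthally averaged log-magnitude spectrum of a square image.

    Bin ``r`` holds the mean of ``log(1 + |F|)`` over pixels at (rounded)
    radius ``r`` from the centred DC position; the log compression tames the
    DC-dominated dynamic range.  Returns a 1-D profile of length
    ``n_bins or (N//2 + 1)``.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape[-2:]
    if h != w:
        raise ValueError(f"radial_spectrum requires a square image, got ({h}, {w})")
    F = np.fft.fftshift(np.fft.fft2(image, axes=(-2, -1)), axes=(-2, -1))
    logmag = np.log1p(np.abs(F))
    cy, cx = h // 2, w // 2
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    max_bins = h // 2 + 1
    n_bins = max_bins if n_bins is None else n_bins
    idx = np.minimum(np.round(r).astype(int), n_bins - 1)
    if logmag.ndim > 2:
        logmag = logmag.reshape(-1, h, w).mean(axis=0)
    sums = np.bincount(idx.ravel(), weights=logmag.ravel(), minlength=n_bins)
    counts = np.bincount(idx.ravel(), minlength=n_bins)
    return sums / np.maximum(counts, 1)


def spectral_distance(test: np.ndarray, reference: np.ndarray,
                      high_freq_only: bool = False) -> float:
    """L2 distance between the radial spectrum profiles of two images.

    With ``high_freq_only`` the comparison is restricted to the upper half of
    the frequency bins, the band where real-valued restoration typically loses
    content.  Zero iff the profiles are identical; symmetric in its arguments.
    """
    p = radial_spectrum(np.asarray(test))
    q = radial_spectrum(np.asarray(reference))
    if high_freq_only:
        lo = len(p) // 2
        p, q = p[lo:], q[lo:]
    return float(np.linalg.norm(p - q))


@dataclass
class EvaluationReport:
    """Per-image and aggregate PSNR / SSIM / spectral distance."""

    psnr_values: list[float] = field(default_factory=list)
    ssim_values: list[float] = field(default_factory=list)
    spectral_values: list[float] = field(default_factory=list)

    def add(self, test: np.ndarray, reference: np.ndarray,
            max_value: float = 1.0) -> None:
        self.psnr_values.append(psnr(test, reference, max_value))
        self.ssim_values.append(ssim(test, reference, max_value))
        self.spectral_values.append(spectral_distance(test, reference))

    @staticmethod
    def _stats(values: list[float]) -> dict:
        arr = np.asarray(values, dtype=float)
        return {"mean": float(arr.mean()), "std": float(arr.std())}

    def summary(self) -> dict:
        return {
            "n_images": len(self.psnr_values),
            "psnr": self._stats(self.psnr_values),
            "ssim": self._stats(self.ssim_values),
            "spectral_distance": self._stats(self.spectral_values),
        }

    def to_dict(self) -> dict:
        out = self.summary()
        out["per_image"] = {
            "psnr": list(map(float, self.psnr_values)),
            "ssim": list(map(float, self.ssim_values)),
            "spectral_distance": list(map(float, self.spectral_values)),
        }
        return out


def three_run_summary(reports: list[EvaluationReport]) -> dict:
    """Mean +/- STD of the per-run means, the multi-seed reporting format."""
    psnr_means = [r.summary()["psnr"]["mean"] for r in reports]
    ssim_means = [r.summary()["ssim"]["mean"] for r in reports]
    return {
        "n_runs": len(reports),
        "psnr_runs": list(map(float, psnr_means)),
        "ssim_runs": list(map(float, ssim_means)),
        "psnr_mean": float(np.mean(psnr_means)),
        "psnr_std": float(np.std(psnr_means)),
        "ssim_mean": float(np.mean(ssim_means)),
        "ssim_std": float(np.std(ssim_means)),
    }
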
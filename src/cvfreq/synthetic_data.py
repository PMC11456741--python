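"""Synthetic SIM-like phantoms and noise models.

Real SR-SIM training data (tubulin filaments, vesicles) is large and external;
this module generates small phantom images with the same gross morphology and
the stated noise families so that every stage of the toolbox is testable
end-to-end:

* ``filaments`` — smooth random-walk curves with a Gaussian line profile,
  emulating tubulin networks;
* ``vesicles`` — randomly placed disks and rings of varied radius;
* ``texture`` — band-limited random fields standing in for natural images.

Noise models: mixed Poisson-Gaussian (signal-dependent shot noise with photon
scale ``p`` plus additive read noise), the real-noise model of reconstructed
SR-SIM inputs, and additive white Gaussian noise specified on the 8-bit scale
(default sigma = 30/255 in normalized units) for the natural-image protocol.
Corrupted images are clipped to [0, 1]; sensors saturate, and clipping is
documented as part of the noise model.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

import tifffile


@dataclass
class PhantomSpec:
    """Recipe for one phantom field of view."""

    kind: str = "filaments"  # filaments | vesicles | texture
    size: int = 64
    n_objects: int = 12
    psf_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("filaments", "vesicles", "texture"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")


@dataclass
class ImagePair:
    """Noisy (or low-resolution) input with its reference image."""

    noisy: np.ndarray
    reference: np.ndarray
    noise_meta: dict = field(default_factory=dict)
    phantom: Optional[dict] = None


def _normalize(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render one phantom image in [0, 1], deterministic per (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    canvas = np.zeros((n, n))
    if spec.n_objects == 0:
        return canvas
    if spec.kind == "filaments":
        # smooth random walks rasterized with sub-pixel steps
        for _ in range(spec.n_objects):
            pos = rng.uniform(0, n, size=2)
            ang = rng.uniform(0, 2 * np.pi)
            curvature = rng.uniform(0.05, 0.25)
            length = int(rng.integers(n, 3 * n))
            amp = rng.uniform(0.6, 1.0)
            for _ in range(length):
                ang += rng.normal(0, curvature)
                pos = pos + np.array([np.cos(ang), np.sin(ang)]) * 0.5
                i, j = int(pos[0]) % n, int(pos[1]) % n
                canvas[i, j] += amp * 0.5
        canvas = np.minimum(canvas, 1.5)
    elif spec.kind == "vesicles":
        yy, xx = np.mgrid[0:n, 0:n]
        for _ in range(spec.n_objects):
            cy, cx = rng.uniform(0, n, size=2)
            radius = rng.uniform(1.5, n / 10)
            amp = rng.uniform(0.5, 1.0)
            r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
            if rng.random() < 0.5:  # filled disk
                canvas += amp * (r <= radius)
            else:  # ring
                canvas += amp * (np.abs(r - radius) <= 1.0)
        canvas = np.minimum(canvas, 1.5)
    else:  # texture: band-limited random field
        field_ = rng.normal(size=(n, n))
        canvas = gaussian_filter(field_, sigma=max(1.0, n / 32), mode="wrap")
    if spec.psf_sigma > 0:
        canvas = gaussian_filter(canvas, sigma=spec.psf_sigma)
    return _normalize(canvas)


def corrupt_poisson_gauss(image: np.ndarray, photon_scale: float = 100.0,
                          sigma: float = 0.02, seed: int = 0,
                          clip: bool = True) -> np.ndarray:
    """Mixed Poisson-Gaussian corruption.

    ``y = Poisson(p * x) / p + N(0, sigma^2)``; variance at signal level x is
    ``x / p + sigma^2``.  Output clipped to [0, 1] unless ``clip=False``.
    """
    if photon_scale <= 0:
        raise ValueError("photon_scale must be positive")
    rng = np.random.default_rng(seed)
    shot = rng.poisson(photon_scale * np.clip(image, 0, None)) / photon_scale
    y = shot + rng.normal(0.0, sigma, size=image.shape)
    return np.clip(y, 0.0, 1.0) if clip else y


def corrupt_awgn(image: np.ndarray, sigma_8bit: float = 30.0, seed: int = 0,
                 clip: bool = True) -> np.ndarray:
    """Additive white Gaussian noise with std given on the 8-bit scale.

    ``sigma_8bit = 30`` corresponds to 30/255 in normalized units.
    """
    rng = np.random.default_rng(seed)
    y = image + rng.normal(0.0, sigma_8bit / 255.0, size=image.shape)
    return np.clip(y, 0.0, 1.0) if clip else y


def make_sr_pair(reference: np.ndarray, method: str = "blur_decimate",
                 blur_sigma: float = 1.0) -> ImagePair:
    """Low-resolution / high-resolution pair at exact factor 2.

    ``blur_decimate`` applies a Gaussian anti-alias filter then 2x decimation;
    ``decimate`` skips the blur (used to verify the decimation grid).
    """
    h, w = reference.shape[-2:]
    if h % 2 or w % 2:
        raise ValueError(f"reference dims ({h}, {w}) must be even")
    if method == "blur_decimate":
        low = gaussian_filter(reference, sigma=blur_sigma)[..., ::2, ::2]
    elif method == "decimate":
        low = reference[..., ::2, ::2]
    else:
        raise ValueError(f"unknown SR pairing method {method!r}")
    return ImagePair(noisy=low.copy(), reference=reference.copy(),
                     noise_meta={"model": "sr_downsample", "method": method,
                                 "blur_sigma": blur_sigma, "factor": 2})


def make_denoising_pair(spec: PhantomSpec, noise_model: str = "poisson_gauss",
                        photon_scale: float = 100.0, sigma: float = 0.02,
                        sigma_8bit: float = 30.0,
                        noise_seed: Optional[int] = None) -> ImagePair:
    """Phantom reference plus its corrupted observation."""
    reference = generate_phantom(spec)
    nseed = spec.seed + 10_000_019 if noise_seed is None else noise_seed
    if noise_model == "poisson_gauss":
        noisy = corrupt_poisson_gauss(reference, photon_scale, sigma, seed=nseed)
        meta = {"model": "poisson_gauss", "photon_scale": photon_scale,
                "sigma": sigma, "seed": nseed}
    elif noise_model == "awgn":
        noisy = corrupt_awgn(reference, sigma_8bit, seed=nseed)
        meta = {"model": "awgn", "sigma": sigma_8bit, "seed": nseed}
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")
    return ImagePair(noisy=noisy, reference=reference, noise_meta=meta,
                     phantom=asdict(spec))


def generate_dataset(n_pairs: int, kind: str = "filaments", size: int = 64,
                     noise_model: str = "poisson_gauss",
                     photon_scale: float = 100.0, sigma: float = 0.02,
                     sigma_8bit: float = 30.0, psf_sigma: float = 1.0,
                     n_objects: int = 12, seed: int = 0,
                     sr: bool = False, sr_blur_sigma: float = 1.0
                     ) -> list[ImagePair]:
    """Generate ``n_pairs`` image pairs; each pair is a distinct field of view.

    Phantom seeds are derived from ``seed`` so two datasets with different
    base seeds never share a field of view (the train/test split protocol).
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1))
                   for s in ss.spawn(n_pairs)]
    pairs = []
    for ps in child_seeds:
        spec = PhantomSpec(kind=kind, size=size, n_objects=n_objects,
                           psf_sigma=psf_sigma, seed=ps)
        if sr:
            ref = generate_phantom(spec)
            pair = make_sr_pair(ref, blur_sigma=sr_blur_sigma)
            pair.phantom = asdict(spec)
        else:
            pair = make_denoising_pair(spec, noise_model=noise_model,
                                       photon_scale=photon_scale, sigma=sigma,
                                       sigma_8bit=sigma_8bit)
        pairs.append(pair)
    return pairs


# -- 16-bit TIFF I/O ---------------------------------------------------------

MANIFEST_VERSION = 1


def _to_uint16(img: np.ndarray) -> np.ndarray:
    return np.round(np.clip(img, 0.0, 1.0) * 65535.0).astype("<u2")


def _from_uint16(arr: np.ndarray) -> np.ndarray:
    return arr.astype(np.float64) / 65535.0


def write_dataset(pairs: list[ImagePair], directory) -> dict:
    """Write 16-bit grayscale TIFF pairs plus a JSON manifest; return manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, pair in enumerate(pairs):
        noisy_name = f"pair{i:04d}_input.tif"
        ref_name = f"pair{i:04d}_reference.tif"
        tifffile.imwrite(directory / noisy_name, _to_uint16(pair.noisy))
        tifffile.imwrite(directory / ref_name, _to_uint16(pair.reference))
        entries.append({"noisy": noisy_name, "reference": ref_name,
                        "noise_meta": pair.noise_meta,
                        "phantom": pair.phantom})
    manifest = {"version": MANIFEST_VERSION, "pairs": entries}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_dataset(directory) -> list[ImagePair]:
    """Read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest.get("version") != MANIFEST_VERSION:
        raise ValueError(f"unsupported manifest version {manifest.get('version')}")
    pairs = []
    for entry in manifest["pairs"]:
        noisy = _from_uint16(tifffile.imread(directory / entry["noisy"]))
        ref = _from_uint16(tifffile.imread(directory / entry["reference"]))
        pairs.append(ImagePair(noisy=noisy, reference=ref,
                               noise_meta=entry.get("noise_meta") or {},
                               phantom=entry.get("phantom")))
    return pairs
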
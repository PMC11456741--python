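"""Desk-scale reference experiments.

These are the package's built-in, CPU-sized analogues of the full-scale
denoising and super-resolution studies: small phantom datasets, narrow
networks, short ADAM schedules.  The protocol is fixed:

* denoising — CV-DDAN (base 8 channels, 4 blocks) on 64x64 filament phantoms
  with mixed Poisson-Gaussian noise (photon scale 100, read noise sigma 0.02),
  200 training / 50 held-out pairs, 10 epochs, batch 1, learning rate 2e-3
  (the short schedule needs many small steps rather than a large-batch one).
  Compared against the noisy input baseline on PSNR and on the radial-spectrum
  distance to the reference (the frequency-preservation statistic).
* super-resolution — CV-SRN (base 8 channels) on clean 32x32 -> 64x64 filament
  pairs (Gaussian anti-alias + 2x decimation), same schedule, compared against
  bicubic upsampling.

Both functions are deterministic given ``seed`` and return plain dicts.
"""

from __future__ import annotations

import numpy as np

from .architectures import ArchitectureConfig
from .metrics import EvaluationReport
from .synthetic_data import generate_dataset
from .training import TrainConfig, baseline_report, evaluate, train

DESK_DENOISE = dict(kind="filaments", size=64, photon_scale=100.0, sigma=0.02,
                    n_train=200, n_test=50, base_channels=8, epochs=10,
                    batch_size=1, learning_rate=2e-3)
DESK_SR = dict(kind="filaments", size=64, sr_blur_sigma=1.0,
               n_train=200, n_test=50, base_channels=8, epochs=10,
               batch_size=2, learning_rate=3e-3)


def _offset(seed: int, k: int) -> int:
    return (seed + k) % (2 ** 31 - 1)


def desk_denoising_experiment(seed: int = 0, arch: str = "cv_ddan",
                              epochs: int | None = None,
                              n_train: int | None = None) -> dict:
    """Train a denoiser at desk scale; report held-out metrics vs baseline."""
    p = DESK_DENOISE
    n_train = p["n_train"] if n_train is None else n_train
    train_pairs = generate_dataset(n_train, kind=p["kind"], size=p["size"],
                                   noise_model="poisson_gauss",
                                   photon_scale=p["photon_scale"],
                                   sigma=p["sigma"], seed=_offset(seed, 1))
    test_pairs = generate_dataset(p["n_test"], kind=p["kind"], size=p["size"],
                                  noise_model="poisson_gauss",
                                  photon_scale=p["photon_scale"],
                                  sigma=p["sigma"], seed=_offset(seed, 2))
    cfg = ArchitectureConfig(name=arch, base_channels=p["base_channels"],
                             seed=_offset(seed, 3))
    tc = TrainConfig(arch=cfg, epochs=p["epochs"] if epochs is None else epochs,
                     batch_size=p["batch_size"],
                     learning_rate=p["learning_rate"], seed=_offset(seed, 4))
    model, history = train(tc, pairs=train_pairs)
    model_report = evaluate(model, pairs=test_pairs)
    noisy_report = baseline_report(test_pairs)
    ms, ns = model_report.summary(), noisy_report.summary()
    return {
        "arch": arch,
        "model_psnr": ms["psnr"]["mean"],
        "baseline_psnr": ns["psnr"]["mean"],
        "psnr_gain": ms["psnr"]["mean"] - ns["psnr"]["mean"],
        "model_ssim": ms["ssim"]["mean"],
        "baseline_ssim": ns["ssim"]["mean"],
        "model_spectral_distance": ms["spectral_distance"]["mean"],
        "baseline_spectral_distance": ns["spectral_distance"]["mean"],
        "final_train_loss": history["train_loss"][-1],
        "initial_train_loss": history["train_loss"][0],
        "n_train": len(train_pairs),
        "n_test": len(test_pairs),
    }


def desk_super_resolution_experiment(seed: int = 0) -> dict:
    """Train CV-SRN at desk scale; report held-out PSNR vs bicubic baseline."""
    p = DESK_SR
    train_pairs = generate_dataset(p["n_train"], kind=p["kind"], size=p["size"],
                                   sr=True, sr_blur_sigma=p["sr_blur_sigma"],
                                   seed=_offset(seed, 11))
    test_pairs = generate_dataset(p["n_test"], kind=p["kind"], size=p["size"],
                                  sr=True, sr_blur_sigma=p["sr_blur_sigma"],
                                  seed=_offset(seed, 12))
    cfg = ArchitectureConfig(name="cv_srn", base_channels=p["base_channels"],
                             seed=_offset(seed, 13))
    tc = TrainConfig(arch=cfg, epochs=p["epochs"], batch_size=p["batch_size"],
                     learning_rate=p["learning_rate"], seed=_offset(seed, 14))
    model, history = train(tc, pairs=train_pairs)
    model_report = evaluate(model, pairs=test_pairs)
    bicubic_report = baseline_report(test_pairs, upsample="bicubic")
    ms, bs = model_report.summary(), bicubic_report.summary()
    return {
        "model_psnr": ms["psnr"]["mean"],
        "bicubic_psnr": bs["psnr"]["mean"],
        "psnr_margin": ms["psnr"]["mean"] - bs["psnr"]["mean"],
        "model_ssim": ms["ssim"]["mean"],
        "bicubic_ssim": bs["ssim"]["mean"],
        "final_train_loss": history["train_loss"][-1],
        "n_train": len(train_pairs),
        "n_test": len(test_pairs),
    }
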
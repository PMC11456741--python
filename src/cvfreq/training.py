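"""Training and evaluation harness.

All networks are trained with the mean squared error loss on the real spatial
output against the reference image, using the ADAM optimizer.  A
frequency-domain MSE option is available behind a flag: with the unnormalized
forward DFT used here, Parseval gives ``freq_MSE = N^2 * spatial_MSE`` on an
``N x N`` image, so the frequency loss is divided by ``N^2`` to keep loss
magnitudes comparable across domains.

Checkpoints are single ``.npz`` files holding the architecture config (JSON),
named parameter arrays, the seed, and a format version.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .architectures import ArchitectureConfig, build_model
from .metrics import EvaluationReport, psnr, three_run_summary
from .modules import Adam, Module
from .synthetic_data import ImagePair, read_dataset

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


@dataclass
class TrainConfig:
    """Hyper-parameters of one training run (all logged into the checkpoint)."""

    arch: ArchitectureConfig
    epochs: int = 10
    batch_size: int = 4
    learning_rate: float = 1e-4
    seed: int = 0
    loss: str = "mse"  # "mse" (spatial) or "fmse" (frequency-domain)
    lr_schedule: str = "constant"  # "constant" or "linear" (decay to 10%)
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    dataset_dir: Optional[str] = None
    checkpoint_path: Optional[str] = None
    validation_fraction: float = 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arch"] = self.arch.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["arch"] = ArchitectureConfig.from_dict(d["arch"])
        return cls(**d)


def save_checkpoint(path, model: Module, train_config: TrainConfig,
                    extra: Optional[dict] = None) -> None:
    meta = {"version": CHECKPOINT_VERSION,
            "train_config": train_config.to_dict(),
            "extra": extra or {}}
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[Module, TrainConfig, dict]:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint format version {meta.get('version')} not supported "
                f"(this build reads version {CHECKPOINT_VERSION})")
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    config = TrainConfig.from_dict(meta["train_config"])
    model = build_model(config.arch)
    model.load_state_dict(state)
    return model, config, meta.get("extra", {})


def _stack_inputs(pairs: Sequence[ImagePair]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.noisy for p in pairs])[:, None, :, :]
    y = np.stack([p.reference for p in pairs])[:, None, :, :]
    return x, y


def _loss(model_out: ad.Tensor, target: np.ndarray, kind: str) -> ad.Tensor:
    diff = model_out - ad.Tensor(target)
    if kind == "mse":
        return ad.mean(ad.square(diff))
    if kind == "fmse":
        fr, fi = ad.fft2_pair(diff)
        n2 = float(np.prod(target.shape[-2:]))
        return (ad.mean(ad.square(fr)) + ad.mean(ad.square(fi))) * (1.0 / n2)
    raise ValueError(f"unknown loss {kind!r}")


def _abort_on_nan(loss_value: float, model: Module, epoch: int) -> None:
    if math.isfinite(loss_value):
        return
    for name, p in model.named_parameters():
        if not np.isfinite(p.data).all():
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}; first non-finite parameter: "
                f"{name}")
    raise FloatingPointError(
        f"non-finite loss at epoch {epoch}; parameters finite, so a forward "
        f"activation overflowed")


def train(config: TrainConfig, pairs: Optional[Sequence[ImagePair]] = None,
          model: Optional[Module] = None) -> tuple[Module, dict]:
    """Train a network; returns (model, history).

    ``pairs`` may be given directly; otherwise ``config.dataset_dir`` is read.
    The run is deterministic given the config and data: parameter init is
    seeded by the architecture config, batch order by ``config.seed``.
    """
    if pairs is None:
        if config.dataset_dir is None:
            raise ValueError("either pairs or config.dataset_dir is required")
        pairs = read_dataset(config.dataset_dir)
    pairs = list(pairs)
    n_val = int(round(config.validation_fraction * len(pairs)))
    val_pairs = pairs[:n_val]
    train_pairs = pairs[n_val:]
    if not train_pairs:
        raise ValueError("no training pairs")
    if model is None:
        model = build_model(config.arch)
    opt = Adam(model.parameters(), lr=config.learning_rate,
               beta1=config.beta1, beta2=config.beta2, eps=config.eps)
    rng = np.random.default_rng(config.seed)
    history = {"train_loss": [], "val_loss": [], "config": config.to_dict()}
    logger.info("training %s: %d pairs, %d epochs, lr=%g, seed=%d",
                config.arch.name, len(train_pairs), config.epochs,
                config.learning_rate, config.seed)
    for epoch in range(config.epochs):
        if config.lr_schedule == "linear" and config.epochs > 1:
            frac = epoch / (config.epochs - 1)
            opt.lr = config.learning_rate * (1.0 - 0.9 * frac)
        elif config.lr_schedule != "constant" and config.lr_schedule != "linear":
            raise ValueError(f"unknown lr_schedule {config.lr_schedule!r}")
        order = rng.permutation(len(train_pairs))
        epoch_losses = []
        for start in range(0, len(train_pairs), config.batch_size):
            batch = [train_pairs[i] for i in order[start:start + config.batch_size]]
            x, y = _stack_inputs(batch)
            opt.zero_grad()
            out = model(x)
            loss = _loss(out, y, config.loss)
            lval = float(loss.data)
            _abort_on_nan(lval, model, epoch)
            if config.learning_rate > 0:
                loss.backward()
                opt.step()
            epoch_losses.append(lval)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if val_pairs:
            xv, yv = _stack_inputs(val_pairs)
            vloss = float(_loss(model(xv), yv, config.loss).data)
            history["val_loss"].append(vloss)
        logger.info("epoch %d/%d train_loss=%.6g%s", epoch + 1, config.epochs,
                    history["train_loss"][-1],
                    f" val_loss={history['val_loss'][-1]:.6g}" if val_pairs else "")
        if config.checkpoint_path:
            save_checkpoint(config.checkpoint_path, model, config,
                            extra={"epoch": epoch + 1,
                                   "history": {k: history[k] for k in
                                               ("train_loss", "val_loss")}})
    return model, history


def predict(model: Module, noisy: np.ndarray) -> np.ndarray:
    """Forward pass on a single image or a batch; returns numpy output."""
    out = model(noisy[None, None] if noisy.ndim == 2 else noisy)
    arr = out.data
    while arr.ndim > noisy.ndim:
        arr = arr[0]
    return arr


def evaluate(model_or_checkpoint, pairs=None, dataset_dir=None,
             max_value: float = 1.0) -> EvaluationReport:
    """Run a model over a test set; per-image and aggregate PSNR/SSIM/spectra."""
    if isinstance(model_or_checkpoint, (str, Path)):
        model, _, _ = load_checkpoint(model_or_checkpoint)
    else:
        model = model_or_checkpoint
    if pairs is None:
        if dataset_dir is None:
            raise ValueError("either pairs or dataset_dir is required")
        pairs = read_dataset(dataset_dir)
    report = EvaluationReport()
    for pair in pairs:
        pred = model(pair.noisy[None, None]).data[0, 0] if isinstance(model, Module) \
            else model(pair.noisy)
        # metrics are computed on the displayable image, as written by restore()
        pred = np.clip(np.asarray(pred), 0.0, max_value)
        report.add(pred, pair.reference, max_value=max_value)
    return report


def baseline_report(pairs, upsample: Optional[str] = None) -> EvaluationReport:
    """Reference-free baseline: the noisy input (optionally upsampled) as prediction."""
    report = EvaluationReport()
    for pair in pairs:
        pred = pair.noisy
        if upsample == "bicubic":
            from scipy.ndimage import zoom
            pred = zoom(pair.noisy, 2, order=3, grid_mode=True, mode="grid-mirror")
        elif upsample == "bilinear":
            from scipy.ndimage import zoom
            pred = zoom(pair.noisy, 2, order=1, grid_mode=True, mode="grid-mirror")
        report.add(pred, pair.reference)
    return report


def evaluate_three_seeds(checkpoints: Sequence, pairs=None,
                         dataset_dir=None) -> dict:
    """Mean +/- STD over runs (the three-seed reporting format)."""
    reports = [evaluate(c, pairs=pairs, dataset_dir=dataset_dir)
               for c in checkpoints]
    return three_run_summary(reports)


# -- image restoration entry point -------------------------------------------

_SUPPORTED_DTYPES = {np.dtype("uint8"): 255.0, np.dtype("uint16"): 65535.0}


def _read_image(path) -> tuple[np.ndarray, float]:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio
        arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB to luminance
        arr = arr.mean(axis=-1).astype(arr.dtype)
    if arr.dtype not in _SUPPORTED_DTYPES:
        raise ValueError(
            f"unsupported bit depth {arr.dtype}; supported: 8-bit and 16-bit "
            f"grayscale")
    scale = _SUPPORTED_DTYPES[arr.dtype]
    return arr.astype(np.float64) / scale, scale


def _write_image(path, img: np.ndarray, scale: float) -> None:
    path = Path(path)
    dtype = np.uint8 if scale == 255.0 else np.uint16
    quant = np.round(np.clip(img, 0.0, 1.0) * scale).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, quant)
    else:
        import imageio.v3 as iio
        iio.imwrite(path, quant)


def restore(checkpoint, input_path, output_path) -> np.ndarray:
    """Read an image, run the checkpointed model, write the restored image.

    Non-divisible inputs are reflect-padded to the architecture's required
    divisibility and cropped back afterwards.  Super-resolution checkpoints
    double the output dimensions.
    """
    model, config, _ = load_checkpoint(checkpoint)
    img, scale = _read_image(input_path)
    h, w = img.shape
    div = config.arch.divisor
    is_sr = config.arch.name == "cv_srn"
    size = max(h, w) if is_sr else 0  # cv_srn additionally requires square input
    ph = (-h) % div if not is_sr else (size + ((-size) % div)) - h
    pw = (-w) % div if not is_sr else (size + ((-size) % div)) - w
    x = ad.Tensor(img[None, None])
    if ph or pw:
        x = ad.pad2d(x, (0, ph, 0, pw), mode="reflect")
    out = model(x).data[0, 0]
    factor = 2 if is_sr else 1
    out = out[:h * factor, :w * factor]
    _write_image(output_path, out, scale)
    return out
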
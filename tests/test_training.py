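"""Training loop, checkpoints, evaluation and the image-restoration entry point."""

import json
import math

import numpy as np
import pytest

from cvfreq.architectures import ARCH_NAMES, ArchitectureConfig, build_model
from cvfreq.synthetic_data import ImagePair, generate_dataset, write_dataset
from cvfreq.training import (TrainConfig, baseline_report, evaluate,
                             evaluate_three_seeds, load_checkpoint, restore,
                             save_checkpoint, train)


def tiny_pairs(n=8, size=32, seed=30, sr=False):
    return generate_dataset(n, size=size, seed=seed, sr=sr)


@pytest.mark.parametrize("name", ARCH_NAMES)
def test_one_epoch_reduces_training_mse(name):
    """Smoke training: every architecture strictly improves on 8 pairs."""
    sr = name == "cv_srn"
    pairs = tiny_pairs(8, 32, seed=31, sr=sr)
    cfg = ArchitectureConfig(name=name, base_channels=4, seed=32)
    tc = TrainConfig(arch=cfg, epochs=2, batch_size=4, learning_rate=1e-3,
                     seed=33)
    model, history = train(tc, pairs=pairs)
    assert history["train_loss"][-1] < history["train_loss"][0]


def test_identical_config_gives_identical_loss_history():
    pairs = tiny_pairs(6, 32, seed=34)
    cfg = ArchitectureConfig(name="unet", base_channels=4, seed=35)
    tc = TrainConfig(arch=cfg, epochs=2, batch_size=3, learning_rate=1e-3,
                     seed=36)
    _, h1 = train(tc, pairs=pairs)
    _, h2 = train(tc, pairs=pairs)
    assert h1["train_loss"] == h2["train_loss"]


def test_zero_learning_rate_freezes_loss():
    pairs = tiny_pairs(4, 32, seed=37)
    cfg = ArchitectureConfig(name="unet", base_channels=4, seed=38)
    tc = TrainConfig(arch=cfg, epochs=3, batch_size=4, learning_rate=0.0,
                     seed=39)
    _, history = train(tc, pairs=pairs)
    assert len(set(np.round(history["train_loss"], 15))) == 1


def test_checkpoint_roundtrip_preserves_model_and_config(tmp_path):
    pairs = tiny_pairs(4, 32, seed=40)
    cfg = ArchitectureConfig(name="attention_unet", base_channels=4, seed=41)
    tc = TrainConfig(arch=cfg, epochs=1, batch_size=4, learning_rate=1e-3,
                     seed=42, checkpoint_path=str(tmp_path / "ckpt.npz"))
    model, _ = train(tc, pairs=pairs)
    loaded, loaded_cfg, extra = load_checkpoint(tmp_path / "ckpt.npz")
    assert loaded_cfg.arch.name == "attention_unet"
    assert extra["epoch"] == 1
    x = pairs[0].noisy
    np.testing.assert_array_equal(model(x).data, loaded(x).data)


def test_checkpoint_architecture_mismatch_is_detected(tmp_path):
    cfg = ArchitectureConfig(name="unet", base_channels=4, seed=43)
    model = build_model(cfg)
    tc = TrainConfig(arch=cfg)
    save_checkpoint(tmp_path / "u.npz", model, tc)
    other = build_model(ArchitectureConfig(name="unet", base_channels=8, seed=43))
    with np.load(tmp_path / "u.npz") as data:
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    with pytest.raises(ValueError, match="shape mismatch"):
        other.load_state_dict(state)


def test_evaluate_identity_and_noisy_baseline():
    pairs = tiny_pairs(3, 32, seed=44)

    class Identity:
        def __call__(self, x):
            import cvfreq.autodiff as ad
            return ad.Tensor(np.asarray(x))

    # reference as prediction -> SSIM exactly 1 per image
    ref_pairs = [ImagePair(noisy=p.reference, reference=p.reference,
                           noise_meta={}) for p in pairs]
    from cvfreq.modules import Module

    class IdentityModule(Module):
        def __call__(self, x):
            import cvfreq.autodiff as ad
            return ad.Tensor(np.asarray(x) if not hasattr(x, "data") else x.data)

    report = evaluate(IdentityModule(), pairs=ref_pairs)
    assert all(s == pytest.approx(1.0) for s in report.ssim_values)
    assert all(math.isinf(p) for p in report.psnr_values)

    # noisy input as prediction reproduces the dataset baseline exactly
    noisy_report = evaluate(IdentityModule(), pairs=pairs)
    base = baseline_report(pairs)
    assert noisy_report.psnr_values == base.psnr_values


def test_evaluate_aggregate_equals_mean_of_per_image():
    pairs = tiny_pairs(3, 32, seed=45)
    base = baseline_report(pairs)
    d = base.to_dict()
    assert d["psnr"]["mean"] == pytest.approx(np.mean(d["per_image"]["psnr"]))


def test_three_seed_reporting_is_reproducible(tmp_path):
    pairs = tiny_pairs(6, 32, seed=46)
    ckpts = []
    for k in range(3):
        cfg = ArchitectureConfig(name="unet", base_channels=4, seed=50 + k)
        tc = TrainConfig(arch=cfg, epochs=1, batch_size=3, learning_rate=1e-3,
                         seed=60 + k, checkpoint_path=str(tmp_path / f"c{k}.npz"))
        train(tc, pairs=pairs[:4])
        ckpts.append(tmp_path / f"c{k}.npz")
    s1 = evaluate_three_seeds(ckpts, pairs=pairs[4:])
    s2 = evaluate_three_seeds(ckpts, pairs=pairs[4:])
    assert s1["n_runs"] == 3
    assert abs(s1["psnr_mean"] - s2["psnr_mean"]) < 1e-9
    assert abs(s1["ssim_std"] - s2["ssim_std"]) < 1e-9


def test_restore_pads_and_crops_non_divisible_input(tmp_path):
    """A 70x70 input runs through reflect padding to the 80x80 divisibility
    target and is cropped back; the result equals a manual pre-padded run."""
    import tifffile
    import cvfreq.autodiff as ad

    pairs = tiny_pairs(4, 64, seed=47)
    cfg = ArchitectureConfig(name="unet", base_channels=4, seed=48)
    tc = TrainConfig(arch=cfg, epochs=1, batch_size=4, learning_rate=1e-3,
                     seed=49, checkpoint_path=str(tmp_path / "r.npz"))
    model, _ = train(tc, pairs=pairs)

    rng = np.random.default_rng(50)
    img = rng.uniform(size=(70, 70))
    tifffile.imwrite(tmp_path / "in.tif",
                     np.round(img * 65535).astype(np.uint16))
    out = restore(tmp_path / "r.npz", tmp_path / "in.tif", tmp_path / "out.tif")
    assert out.shape == (70, 70)
    written = tifffile.imread(tmp_path / "out.tif")
    assert written.shape == (70, 70) and written.dtype == np.uint16

    # oracle: reflect-pad to the same 80x80 target by hand, forward, crop
    q = np.round(img * 65535) / 65535
    pre = ad.pad2d(ad.Tensor(q[None, None]), (0, 10, 0, 10), mode="reflect")
    full = model(pre).data[0, 0][:70, :70]
    np.testing.assert_allclose(out, full, atol=1e-12)


def test_restore_rejects_unsupported_bit_depth(tmp_path):
    import tifffile
    cfg = ArchitectureConfig(name="unet", base_channels=4, seed=51)
    tc = TrainConfig(arch=cfg)
    save_checkpoint(tmp_path / "m.npz", build_model(cfg), tc)
    tifffile.imwrite(tmp_path / "f32.tif", np.zeros((32, 32), dtype=np.float32))
    with pytest.raises(ValueError, match="8-bit and 16-bit"):
        restore(tmp_path / "m.npz", tmp_path / "f32.tif", tmp_path / "o.tif")


def test_blank_image_restores_to_finite_output(tmp_path):
    import tifffile
    cfg = ArchitectureConfig(name="unet", base_channels=4, seed=52)
    save_checkpoint(tmp_path / "m.npz", build_model(cfg), TrainConfig(arch=cfg))
    tifffile.imwrite(tmp_path / "blank.tif", np.zeros((32, 32), dtype=np.uint16))
    out = restore(tmp_path / "m.npz", tmp_path / "blank.tif", tmp_path / "o.tif")
    assert np.isfinite(out).all()


def test_nan_abort_names_a_parameter():
    pairs = tiny_pairs(2, 32, seed=53)
    cfg = ArchitectureConfig(name="unet", base_channels=4, seed=54)
    model = build_model(cfg)
    first = next(iter(model.named_parameters()))[0]
    for _, p in model.named_parameters():
        p.data = np.full_like(p.data, np.nan)
        break
    tc = TrainConfig(arch=cfg, epochs=1, batch_size=2, learning_rate=1e-3)
    with pytest.raises(FloatingPointError, match="non-finite"):
        train(tc, pairs=pairs, model=model)


def test_frequency_domain_loss_option_trains():
    pairs = tiny_pairs(4, 32, seed=55)
    cfg = ArchitectureConfig(name="unet", base_channels=4, seed=56)
    tc = TrainConfig(arch=cfg, epochs=2, batch_size=4, learning_rate=1e-3,
                     seed=57, loss="fmse")
    _, history = train(tc, pairs=pairs)
    assert history["train_loss"][-1] < history["train_loss"][0]
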
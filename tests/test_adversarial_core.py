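"""Adversarial losses, discriminator behavior, and the training engine's
schedule, determinism and detachment contracts."""

import csv

import numpy as np
import pytest

from dwicycle._autodiff import Tensor
from dwicycle.adversarial_core import (
    PatchDiscriminator,
    TrainConfig,
    cycle_loss,
    denormalize_from_unit,
    dual_contrast_disc_loss,
    generator_adv_loss,
    normalize_to_unit,
    scaled_down_configs,
    synthesize,
    train,
)
from dwicycle.generator_net import Generator, GeneratorConfig

# ---------------------------------------------------------------------------
# independent minimal CycleGAN loss formulas (oracle; plain numpy)
# ---------------------------------------------------------------------------


def plain_lsgan_disc_loss(real, fake):
    return np.mean((real - 1.0) ** 2) + np.mean(fake**2)


def plain_lsgan_gen_loss(fake):
    return np.mean((fake - 1.0) ** 2)


def plain_cycle_loss(x, rec_x, y, rec_y, lam):
    return lam * (np.mean(np.abs(x - rec_x)) + np.mean(np.abs(y - rec_y)))


# ---------------------------------------------------------------------------
# discriminator
# ---------------------------------------------------------------------------


def test_score_grid_shape_follows_receptive_field_arithmetic():
    """4 stride-2,2,2,1 layers plus the head map 256 -> 30 and 64 -> 6."""
    d = PatchDiscriminator(ndf=4, seed=0)
    assert d(np.zeros((64, 64))).shape == (1, 1, 6, 6)
    assert d(np.zeros((256, 256))).shape == (1, 1, 30, 30)


def test_zero_weights_give_constant_bias_scores(rng):
    d = PatchDiscriminator(ndf=4, seed=0)
    for name, p in d.named_parameters():
        p.data[:] = 0.0
    d.head.bias.data[:] = 0.7
    out = d(rng.normal(size=(64, 64))).data
    np.testing.assert_allclose(out, 0.7, atol=1e-12)


def test_score_grid_is_shift_equivariant_in_the_interior(rng):
    """Translating the input by one patch stride (8 px) shifts the score
    grid by one cell wherever the 70-px receptive field stays inside the
    image (fully-convolutional property; norm-free variant, since
    instance norm couples every cell to the image boundary)."""
    d = PatchDiscriminator(ndf=2, seed=1, norm=False)
    x = rng.normal(size=(128, 128))
    s1 = d(x).data[0, 0]
    s2 = d(np.roll(x, 8, axis=0)).data[0, 0]
    assert s1.shape == (14, 14)
    interior = slice(5, 9)
    np.testing.assert_allclose(s1[interior, interior], s2[6:10, interior], atol=1e-10)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def test_perfect_discriminator_has_zero_loss():
    ones, zeros = np.ones((1, 1, 4, 4)), np.zeros((1, 1, 4, 4))
    assert dual_contrast_disc_loss(ones, zeros, zeros, 1.0).item() == 0.0


def test_fully_fooled_discriminator_loss_is_three():
    zeros, ones = np.zeros((1, 1, 4, 4)), np.ones((1, 1, 4, 4))
    assert dual_contrast_disc_loss(zeros, ones, ones, 1.0).item() == pytest.approx(3.0)


def test_zero_negative_weight_reduces_to_plain_cyclegan(rng):
    for _ in range(5):
        real = rng.normal(size=(1, 1, 6, 6))
        fake = rng.normal(size=(1, 1, 6, 6))
        neg = rng.normal(size=(1, 1, 6, 6))
        mine = dual_contrast_disc_loss(real, fake, neg, neg_weight=0.0).item()
        assert mine == pytest.approx(plain_lsgan_disc_loss(real, fake), abs=1e-12)


def test_generator_adv_loss_matches_independent_formula(rng):
    assert generator_adv_loss(np.ones((2, 2))).item() == 0.0
    assert generator_adv_loss(np.zeros((2, 2))).item() == 1.0
    for _ in range(5):
        fake = rng.normal(size=(1, 1, 6, 6))
        assert generator_adv_loss(fake).item() == pytest.approx(
            plain_lsgan_gen_loss(fake), abs=1e-12
        )


def test_cycle_loss_values_and_symmetry(rng):
    x = rng.random((8, 8))
    y = rng.random((8, 8))
    assert cycle_loss(x, x, y, y, 10.0).item() == 0.0
    off = cycle_loss(x, x + 0.5, y, y - 0.5, 10.0).item()
    assert off == pytest.approx(10.0, abs=1e-12)
    a = cycle_loss(x, x + 0.1, y, y + 0.3, 7.0).item()
    b = cycle_loss(y, y + 0.3, x, x + 0.1, 7.0).item()
    assert a == pytest.approx(b, abs=1e-12)
    assert a >= 0


def test_losses_nonnegative_random_grids(rng):
    for _ in range(10):
        r, f, n = (rng.normal(size=(3, 3)) for _ in range(3))
        assert dual_contrast_disc_loss(r, f, n, 1.0).item() >= 0
        assert generator_adv_loss(f).item() >= 0


def test_gradient_isolation_between_players(rng):
    """Discriminator loss on detached fakes sends no gradient into the
    generator, and a frozen discriminator gets none from the generator
    loss."""
    gcfg = GeneratorConfig(f0=8, vit_blocks=0, fp=16, fv=64, n_heads=4, image_size=(32, 32))
    gen = Generator(gcfg, seed=0)
    disc = PatchDiscriminator(ndf=4, seed=0)
    x = Tensor(rng.normal(size=(1, 1, 32, 32)))

    fake = gen(x).detach()
    loss_d = dual_contrast_disc_loss(disc(x), disc(fake), None, 0.0)
    loss_d.backward()
    assert all(p.grad is None for p in gen.parameters())
    assert any(p.grad is not None for p in disc.parameters())

    from dwicycle._autodiff import set_requires_grad

    for p in gen.parameters() + disc.parameters():
        p.grad = None
    set_requires_grad(disc, False)
    generator_adv_loss(disc(gen(x))).backward()
    assert all(p.grad is None for p in disc.parameters())
    assert any(p.grad is not None for p in gen.parameters())


# ---------------------------------------------------------------------------
# training engine
# ---------------------------------------------------------------------------


def _read_log(path):
    with open(path) as fh:
        return list(csv.DictReader(fh))


def _quick_cfgs(steps, seed=0, **over):
    gen_cfg, train_cfg = scaled_down_configs(seed=seed, steps=steps)
    for k, v in over.items():
        setattr(train_cfg, k, v)
    return gen_cfg, train_cfg


def test_update_ratio_is_five_to_one(tiny_dataset, tmp_path):
    root, _ = tiny_dataset
    gen_cfg, train_cfg = _quick_cfgs(steps=30)
    state = train(root, gen_cfg, train_cfg, tmp_path / "run")
    assert state.gen_updates == 30
    assert state.disc_updates == 6
    rows = _read_log(tmp_path / "run" / "loss_log.csv")
    gen_rows = [r for r in rows if r["loss_G_adv"] != ""]
    disc_rows = [r for r in rows if r["loss_Dx"] != ""]
    assert len(gen_rows) == 30 and len(disc_rows) == 6


@pytest.mark.parametrize("k", [1, 3])
def test_update_ratio_generalizes(tiny_dataset, tmp_path, k):
    root, _ = tiny_dataset
    gen_cfg, train_cfg = _quick_cfgs(steps=6, gen_steps_per_disc_step=k)
    state = train(root, gen_cfg, train_cfg, tmp_path / f"run{k}")
    assert state.gen_updates // state.disc_updates == k


def test_identical_seeds_give_identical_loss_logs(tiny_dataset, tmp_path):
    root, _ = tiny_dataset
    for tag in ("a", "b"):
        gen_cfg, train_cfg = _quick_cfgs(steps=12, seed=7)
        train(root, gen_cfg, train_cfg, tmp_path / tag)
    log_a = (tmp_path / "a" / "loss_log.csv").read_text()
    log_b = (tmp_path / "b" / "loss_log.csv").read_text()
    assert log_a == log_b
    gen_cfg, train_cfg = _quick_cfgs(steps=12, seed=8)
    train(root, gen_cfg, train_cfg, tmp_path / "c")
    assert (tmp_path / "c" / "loss_log.csv").read_text() != log_a


def test_empty_dataset_rejected(tmp_path):
    (tmp_path / "trainA").mkdir()
    (tmp_path / "trainB").mkdir()
    gen_cfg, train_cfg = _quick_cfgs(steps=1)
    with pytest.raises(ValueError, match="no PNG images"):
        train(tmp_path, gen_cfg, train_cfg, tmp_path / "out")


def test_synthesize_counts_and_intensity_range(tiny_dataset, tmp_path):
    root, _ = tiny_dataset
    gen_cfg, train_cfg = _quick_cfgs(steps=10)
    train(root, gen_cfg, train_cfg, tmp_path / "run")
    out = synthesize(tmp_path / "run" / "checkpoint_final.npz", root / "testA", tmp_path / "synth")
    n_in = len(list((root / "testA").glob("*.png")))
    assert len(out) == n_in > 0
    from dwicycle.cli_io import read_png

    for f in out:
        pixels, depth = read_png(f)
        assert depth == 16
        assert pixels.min() >= 0 and pixels.max() <= 65535


def test_normalization_roundtrip(rng):
    img = rng.random((16, 16)) * 4000
    unit = normalize_to_unit(img, 4000)
    assert unit.min() >= -1 and unit.max() <= 1
    np.testing.assert_allclose(denormalize_from_unit(unit, 4000), img, atol=1e-9)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(lambda_cyc=0.0)
    with pytest.raises(ValueError):
        TrainConfig(gen_steps_per_disc_step=0)
    with pytest.raises(ValueError):
        TrainConfig(adv_loss="wasserstein")


def test_cross_entropy_losses_are_finite_and_positive(rng):
    r, f, n = (rng.normal(size=(3, 3)) for _ in range(3))
    d = dual_contrast_disc_loss(r, f, n, 1.0, kind="cross_entropy").item()
    g = generator_adv_loss(f, kind="cross_entropy").item()
    assert np.isfinite(d) and d > 0
    assert np.isfinite(g) and g > 0
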
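"""Discriminators, dual-contrast and cycle losses, and the training engine.

The framework is a CycleGAN: generator G maps domain A (lower b-value,
noisier) to domain B (higher b-value), F maps back, and patch
discriminators Dx/Dy judge realness of domain-A/domain-B images.  Two
departures from the plain CycleGAN recipe define this model:

* **Dual-contrast discriminator loss.**  Each discriminator also sees
  randomly drawn *source-domain* images as negatives (class 0), so the
  generator cannot fool it by making minimal edits that leave the output
  near the source domain.  In least-squares form:

      L_Dy = mean((Dy(y) - 1)^2) + mean(Dy(G(x))^2)
             + neg_weight * mean(Dy(x')^2)

  and symmetrically for Dx.  ``neg_weight = 0`` recovers the standard
  CycleGAN discriminator loss.

* **5:1 update schedule.**  Five optimizer steps on the generators (on
  fresh batches) are followed by one step on the discriminators.

Cycle consistency is the usual L1 round-trip penalty scaled by
``lambda_cyc`` (default 10); Adam runs with beta1 = 0.5.  Training is
single-threaded float64 numpy, so two runs with the same seed and config
produce identical loss logs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._autodiff import Adam, Conv2d, InstanceNorm2d, Module, Tensor, set_requires_grad
from .generator_net import Generator, GeneratorConfig

__all__ = [
    "TrainConfig",
    "PatchDiscriminator",
    "generator_adv_loss",
    "dual_contrast_disc_loss",
    "cycle_loss",
    "TrainingDiverged",
    "CycleState",
    "scaled_down_configs",
    "train",
    "synthesize",
    "load_checkpoint",
    "normalize_to_unit",
    "denormalize_from_unit",
]


@dataclass
class TrainConfig:
    """Optimization protocol: lambda_cyc is the cycle-consistency weight,
    beta1 the Adam first-moment decay, and gen_steps_per_disc_step the
    generator:discriminator update ratio (five generator iterations per
    discriminator iteration by default)."""

    lambda_cyc: float = 10.0
    beta1: float = 0.5
    epochs: int = 200
    batch_size: int = 1
    gen_steps_per_disc_step: int = 5
    learning_rate: float = 2e-4
    neg_weight: float = 1.0
    seed: int = 0
    adv_loss: str = "least_squares"  # or "cross_entropy"
    use_dcl: bool = True
    identity_weight: float = 0.0
    ndf: int = 64
    lr_decay: bool = True
    max_steps: int = 0  # generator updates; 0 -> epochs * dataset length
    checkpoint_every: int = 0  # 0 -> final checkpoint only

    def __post_init__(self):
        if self.lambda_cyc <= 0:
            raise ValueError("lambda_cyc must be > 0")
        if self.gen_steps_per_disc_step < 1:
            raise ValueError("gen_steps_per_disc_step must be >= 1")
        if self.adv_loss not in ("least_squares", "cross_entropy"):
            raise ValueError(f"unknown adv_loss {self.adv_loss!r}")


class TrainingDiverged(RuntimeError):
    """Raised when a loss becomes non-finite; carries the forensic dump path."""


class PatchDiscriminator(Module):
    """PatchGAN discriminator: 4 convolution layers (stride 2,2,2,1) with
    instance norm and leaky-ReLU 0.2, then a 1-channel score head.  Each
    output score judges a 70x70 receptive field; a 256x256 input yields a
    30x30 score grid of unbounded logits."""

    def __init__(self, in_channels: int = 1, ndf: int = 64, seed: int = 0, norm: bool = True):
        rng = np.random.default_rng(seed)
        self.c1 = Conv2d(in_channels, ndf, 4, rng, stride=2, padding=1)
        self.c2 = Conv2d(ndf, ndf * 2, 4, rng, stride=2, padding=1)
        self.n2 = InstanceNorm2d(ndf * 2) if norm else None
        self.c3 = Conv2d(ndf * 2, ndf * 4, 4, rng, stride=2, padding=1)
        self.n3 = InstanceNorm2d(ndf * 4) if norm else None
        self.c4 = Conv2d(ndf * 4, ndf * 8, 4, rng, stride=1, padding=1)
        self.n4 = InstanceNorm2d(ndf * 8) if norm else None
        self.head = Conv2d(ndf * 8, 1, 4, rng, stride=1, padding=1)

    def forward(self, x) -> Tensor:
        x = Generator._as_tensor(x)
        h = self.c1(x).leaky_relu(0.2)
        for conv, nm in ((self.c2, self.n2), (self.c3, self.n3), (self.c4, self.n4)):
            h = conv(h)
            if nm is not None:
                h = nm(h)
            h = h.leaky_relu(0.2)
        return self.head(h)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def generator_adv_loss(fake_scores, kind: str = "least_squares") -> Tensor:
    """Adversarial term pushing generated images toward 'real' (class 1)."""
    s = _as_tensor(fake_scores)
    if kind == "least_squares":
        return ((s - 1.0) ** 2).mean()
    return (-s).softplus().mean()  # -log sigmoid(s)


def dual_contrast_disc_loss(
    real_scores, fake_scores, neg_scores=None, neg_weight: float = 1.0,
    kind: str = "least_squares",
) -> Tensor:
    """Discriminator loss with source-domain negatives.

    Real images are class 1; synthesized images *and* raw source-domain
    samples are class 0.  ``neg_scores=None`` or ``neg_weight=0`` gives
    the plain CycleGAN discriminator loss.
    """
    r, f = _as_tensor(real_scores), _as_tensor(fake_scores)
    if kind == "least_squares":
        loss = ((r - 1.0) ** 2).mean() + (f**2).mean()
        if neg_scores is not None and neg_weight != 0:
            loss = loss + neg_weight * (_as_tensor(neg_scores) ** 2).mean()
    else:
        loss = (-r).softplus().mean() + f.softplus().mean()
        if neg_scores is not None and neg_weight != 0:
            loss = loss + neg_weight * _as_tensor(neg_scores).softplus().mean()
    return loss


def cycle_loss(x, rec_x, y, rec_y, lambda_cyc: float = 10.0) -> Tensor:
    """lambda_cyc * (mean|x - F(G(x))| + mean|y - G(F(y))|)."""
    x, rec_x, y, rec_y = map(_as_tensor, (x, rec_x, y, rec_y))
    if x.shape != rec_x.shape or y.shape != rec_y.shape:
        raise ValueError("cycle_loss shape mismatch")
    return lambda_cyc * ((x - rec_x).abs().mean() + (y - rec_y).abs().mean())


def identity_loss(y, g_of_y, x, f_of_x, weight: float) -> Tensor:
    y, g_of_y, x, f_of_x = map(_as_tensor, (y, g_of_y, x, f_of_x))
    return weight * ((y - g_of_y).abs().mean() + (x - f_of_x).abs().mean())


# ---------------------------------------------------------------------------
# intensity normalization
# ---------------------------------------------------------------------------


def normalize_to_unit(pixels: np.ndarray, data_max: float) -> np.ndarray:
    """Map [0, data_max] linearly onto [-1, 1] (the generator's tanh range)."""
    return np.asarray(pixels, dtype=np.float64) / data_max * 2.0 - 1.0


def denormalize_from_unit(unit: np.ndarray, data_max: float) -> np.ndarray:
    return (np.clip(unit, -1.0, 1.0) + 1.0) / 2.0 * data_max


# ---------------------------------------------------------------------------
# training engine
# ---------------------------------------------------------------------------


def scaled_down_configs(seed: int = 0, steps: int = 600) -> tuple[GeneratorConfig, TrainConfig]:
    """Desk-scale study conditions for CPU experiments: 32x32 phantoms with
    proportionally narrow widths (f0=8, one ViT block, fv=64, 16-filter
    discriminators) and a shorter, slightly hotter optimization (600
    generator updates at lr 1e-3).  The protocol — batch 1, lambda=10,
    beta1=0.5, 5:1 update ratio, dual-contrast negatives — is unchanged
    from the full-scale recipe."""
    gen_cfg = GeneratorConfig(
        f0=8, depth=4, vit_blocks=1, fp=16, fv=64, n_heads=4, image_size=(32, 32)
    )
    train_cfg = TrainConfig(
        max_steps=steps, learning_rate=1e-3, ndf=16, seed=seed, lr_decay=True
    )
    return gen_cfg, train_cfg


@dataclass
class CycleState:
    """Networks, optimizers and step counters of one training run."""

    G: Generator  # A -> B
    F: Generator  # B -> A
    Dx: PatchDiscriminator  # judges domain A
    Dy: PatchDiscriminator  # judges domain B
    opt_G: Adam
    opt_D: Adam
    gen_updates: int = 0
    disc_updates: int = 0


def _load_domain(folder: Path) -> list[np.ndarray]:
    from .cli_io import read_png

    files = sorted(folder.glob("*.png"))
    if not files:
        raise ValueError(f"no PNG images found in {folder}")
    return [read_png(f)[0] for f in files]


def _init_state(gen_cfg: GeneratorConfig, cfg: TrainConfig) -> CycleState:
    from .cli_io import derive_seed

    G = Generator(gen_cfg, seed=derive_seed(cfg.seed, "G"))
    F = Generator(gen_cfg, seed=derive_seed(cfg.seed, "F"))
    Dx = PatchDiscriminator(gen_cfg.in_channels, cfg.ndf, seed=derive_seed(cfg.seed, "Dx"))
    Dy = PatchDiscriminator(gen_cfg.in_channels, cfg.ndf, seed=derive_seed(cfg.seed, "Dy"))
    opt_G = Adam(G.parameters() + F.parameters(), cfg.learning_rate, beta1=cfg.beta1)
    opt_D = Adam(Dx.parameters() + Dy.parameters(), cfg.learning_rate, beta1=cfg.beta1)
    return CycleState(G, F, Dx, Dy, opt_G, opt_D)


def train(
    data_dir,
    gen_cfg: GeneratorConfig,
    cfg: TrainConfig,
    out_dir,
    log_every: int = 0,
) -> CycleState:
    """Run the adversarial optimization protocol.

    Reads unpaired ``trainA``/``trainB`` PNG folders under ``data_dir``,
    runs generator updates (batch size 1 on fresh random pairs) with one
    discriminator update after every ``gen_steps_per_disc_step`` of them,
    and writes ``loss_log.csv`` (one row per optimizer event), periodic
    checkpoints and a provenance record into ``out_dir``.
    """
    from .cli_io import get_logger, write_provenance

    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger = get_logger("dwicycle.train", jsonl_path=out_dir / "train_log.jsonl")

    imgs_a = [normalize_to_unit(p, 65535.0) for p in _load_domain(data_dir / "trainA")]
    imgs_b = [normalize_to_unit(p, 65535.0) for p in _load_domain(data_dir / "trainB")]

    state = _init_state(gen_cfg, cfg)
    rng = np.random.default_rng(cfg.seed)
    steps_per_epoch = max(len(imgs_a), len(imgs_b)) // cfg.batch_size
    n_gen = cfg.max_steps if cfg.max_steps else cfg.epochs * steps_per_epoch
    k = cfg.gen_steps_per_disc_step
    base_lr = cfg.learning_rate

    write_provenance(
        out_dir,
        {"generator": asdict(gen_cfg), "train": asdict(cfg), "data_dir": str(data_dir)},
        cfg.seed,
        n_generator_updates=n_gen,
    )

    log_path = out_dir / "loss_log.csv"
    log_fh = open(log_path, "w", newline="")
    writer = csv.writer(log_fh)
    writer.writerow(["step", "epoch", "loss_G_adv", "loss_F_adv", "loss_cyc", "loss_Dx", "loss_Dy"])
    event = 0

    def _check_finite(value: float, tag: str, batch):
        if np.isfinite(value):
            return
        dump = out_dir / f"diverged_{tag}_event{event}.npz"
        np.savez(dump, **batch)
        log_fh.close()
        raise TrainingDiverged(
            f"non-finite {tag} loss at optimizer event {event}; offending batch dumped to {dump}"
        )

    def _sample(pool: list[np.ndarray]) -> np.ndarray:
        return pool[int(rng.integers(len(pool)))]

    for step in range(1, n_gen + 1):
        if cfg.lr_decay and n_gen > 1:
            frac = (step - 1) / n_gen
            lr = base_lr if frac < 0.5 else base_lr * max(0.0, 2.0 * (1.0 - frac))
            lr = max(lr, base_lr * 1e-3)
            state.opt_G.lr = state.opt_D.lr = lr
        epoch = (step - 1) // max(steps_per_epoch, 1)

        # ---- generator update (discriminators frozen) ----
        x, y = _sample(imgs_a), _sample(imgs_b)
        set_requires_grad(state.Dx, False)
        set_requires_grad(state.Dy, False)
        state.opt_G.zero_grad()
        xt, yt = Tensor(x[None, None]), Tensor(y[None, None])
        fake_y = state.G(xt)
        fake_x = state.F(yt)
        rec_x = state.F(fake_y)
        rec_y = state.G(fake_x)
        loss_g_adv = generator_adv_loss(state.Dy(fake_y), cfg.adv_loss)
        loss_f_adv = generator_adv_loss(state.Dx(fake_x), cfg.adv_loss)
        loss_cyc = cycle_loss(xt, rec_x, yt, rec_y, cfg.lambda_cyc)
        total = loss_g_adv + loss_f_adv + loss_cyc
        if cfg.identity_weight > 0:
            total = total + identity_loss(yt, state.G(yt), xt, state.F(xt), cfg.identity_weight)
        total.backward()
        state.opt_G.step()
        set_requires_grad(state.Dx, True)
        set_requires_grad(state.Dy, True)
        state.gen_updates += 1
        event += 1
        _check_finite(total.item(), "generator", {"x": x, "y": y})
        writer.writerow(
            [event, epoch, f"{loss_g_adv.item():.10g}", f"{loss_f_adv.item():.10g}",
             f"{loss_cyc.item():.10g}", "", ""]
        )

        # ---- discriminator update after every k generator updates ----
        if step % k == 0:
            x, y = _sample(imgs_a), _sample(imgs_b)
            x_neg, y_neg = _sample(imgs_a), _sample(imgs_b)
            set_requires_grad(state.G, False)
            set_requires_grad(state.F, False)
            state.opt_D.zero_grad()
            fake_y = state.G(Tensor(x[None, None])).detach()
            fake_x = state.F(Tensor(y[None, None])).detach()
            set_requires_grad(state.G, True)
            set_requires_grad(state.F, True)
            neg_w = cfg.neg_weight if cfg.use_dcl else 0.0
            # Dy judges domain B; its negatives are raw domain-A images (x')
            loss_dy = dual_contrast_disc_loss(
                state.Dy(Tensor(y[None, None])), state.Dy(fake_y),
                state.Dy(Tensor(x_neg[None, None])), neg_w, cfg.adv_loss,
            )
            loss_dx = dual_contrast_disc_loss(
                state.Dx(Tensor(x[None, None])), state.Dx(fake_x),
                state.Dx(Tensor(y_neg[None, None])), neg_w, cfg.adv_loss,
            )
            (loss_dx + loss_dy).backward()
            state.opt_D.step()
            state.disc_updates += 1
            event += 1
            _check_finite(loss_dx.item() + loss_dy.item(), "discriminator", {"x": x, "y": y})
            writer.writerow(
                [event, epoch, "", "", "", f"{loss_dx.item():.10g}", f"{loss_dy.item():.10g}"]
            )

        if log_every and step % log_every == 0:
            logger.info(
                "step %d/%d: G_adv %.4f F_adv %.4f cyc %.4f",
                step, n_gen, loss_g_adv.item(), loss_f_adv.item(), loss_cyc.item(),
            )
        if cfg.checkpoint_every and step % cfg.checkpoint_every == 0:
            save_checkpoint(state, gen_cfg, cfg, out_dir / f"checkpoint_{step:06d}.npz")

    log_fh.close()
    save_checkpoint(state, gen_cfg, cfg, out_dir / "checkpoint_final.npz")
    return state


# ---------------------------------------------------------------------------
# checkpoints and synthesis
# ---------------------------------------------------------------------------


def save_checkpoint(state: CycleState, gen_cfg: GeneratorConfig, cfg: TrainConfig, path) -> None:
    """Self-describing archive: configs, all weights, optimizer state, counters."""
    arrays = {}
    for tag, module in (("G", state.G), ("F", state.F), ("Dx", state.Dx), ("Dy", state.Dy)):
        for name, arr in module.state_dict().items():
            arrays[f"{tag}/{name}"] = arr
    for tag, opt in (("optG", state.opt_G), ("optD", state.opt_D)):
        sd = opt.state_dict()
        for i, (m, v) in enumerate(zip(sd["m"], sd["v"])):
            arrays[f"{tag}/m/{i}"] = m
            arrays[f"{tag}/v/{i}"] = v
    meta = {
        "generator_config": asdict(gen_cfg),
        "train_config": asdict(cfg),
        "gen_updates": state.gen_updates,
        "disc_updates": state.disc_updates,
        "opt_t": {"G": state.opt_G.t, "D": state.opt_D.t},
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta, default=list).encode(), dtype=np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> tuple[CycleState, GeneratorConfig, TrainConfig]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["meta_json"]).decode())
        gen_cfg = GeneratorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in meta["generator_config"].items()})
        cfg = TrainConfig(**meta["train_config"])
        state = _init_state(gen_cfg, cfg)
        for tag, module in (("G", state.G), ("F", state.F), ("Dx", state.Dx), ("Dy", state.Dy)):
            prefix = f"{tag}/"
            sd = {k[len(prefix):]: archive[k] for k in archive.files if k.startswith(prefix)
                  and not k.startswith(("optG/", "optD/"))}
            module.load_state_dict(sd)
        for tag, opt in (("optG", state.opt_G), ("optD", state.opt_D)):
            n = len(opt.params)
            opt.load_state_dict(
                {"t": meta["opt_t"]["G" if tag == "optG" else "D"],
                 "m": [archive[f"{tag}/m/{i}"] for i in range(n)],
                 "v": [archive[f"{tag}/v/{i}"] for i in range(n)]}
            )
        state.gen_updates = int(meta["gen_updates"])
        state.disc_updates = int(meta["disc_updates"])
    return state, gen_cfg, cfg


def synthesize(checkpoint_path, in_dir, out_dir) -> list[Path]:
    """Apply the trained A->B generator to every PNG in ``in_dir``.

    The inverse of the training-time normalization is applied before
    writing, so outputs land on the same 16-bit scale as the inputs.
    """
    from .cli_io import read_png, write_png

    state, _, _ = load_checkpoint(checkpoint_path)
    set_requires_grad(state.G, False)  # inference only: skip graph building
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for f in sorted(in_dir.glob("*.png")):
        pixels, _ = read_png(f)
        unit = normalize_to_unit(pixels, 65535.0)
        out = state.G(unit).data[0, 0]
        write_png(denormalize_from_unit(out, 65535.0), out_dir / f.name, bit_depth=16)
        written.append(out_dir / f.name)
    return written
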
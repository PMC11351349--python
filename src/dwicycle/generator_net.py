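"""U-net generator with CBAM attention and a rezero ViT bottleneck.

The generator is a four-level encoder/decoder: each encoder block halves
the spatial dimensions with a stride-2 convolution while doubling the
channel count (f0 -> 2*f0 -> ... -> f0*2^depth), applies instance
normalization, ReLU and a CBAM attention block, and hands its
pre-downsample features to the matching decoder level through a skip
connection.  The bottleneck flattens the coarsest feature grid into a
token sequence, concatenates a 2D Fourier positional embedding to every
token, linearly projects into a transformer working width, and runs a
stack of rezero transformer encoder blocks:

    t <- t + alpha_attn * Attention(LN(t))
    t <- t + alpha_mlp  * MLP(LN(t))

with the trainable scalars alpha initialized to 0, so the whole stack is
exactly the identity between its in/out projections at initialization
(the rezero scheme).  The decoder mirrors the encoder with transposed
convolutions and ends in a tanh onto [-1, 1].

CBAM applies a channel gate — sigmoid(MLP(avgpool) + MLP(maxpool)) — and
then a spatial gate — sigmoid(conv([channel-mean; channel-max])) — both
strictly inside (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import (
    Conv2d,
    ConvTranspose2d,
    InstanceNorm2d,
    LayerNorm,
    Linear,
    Module,
    Parameter,
    Tensor,
    concat,
    softmax_last,
)

__all__ = [
    "GeneratorConfig",
    "Generator",
    "CBAM",
    "VitBottleneck",
    "fourier_pos_embedding",
    "parameter_breakdown",
]


@dataclass
class GeneratorConfig:
    """Architecture hyperparameters for the generator.

    ``f0`` is the channel width after the preprocessing layer; each of
    the ``depth`` encoder levels doubles it.  ``fp`` is the Fourier
    positional-embedding width (multiple of 4), ``fv`` the transformer
    working width (multiple of ``n_heads``).  ``depth=4`` and
    ``vit_blocks=12`` reproduce the reference architecture;
    ``use_vit``/``use_cbam`` toggle the ablation variants.
    """

    f0: int = 64
    depth: int = 4
    vit_blocks: int = 12
    fp: int = 64
    fv: int = 512
    n_heads: int = 8
    alpha_init: float = 0.0
    image_size: tuple = (256, 256)
    in_channels: int = 1
    out_channels: int = 1
    mlp_ratio: int = 4
    cbam_reduction: int = 8
    use_vit: bool = True
    use_cbam: bool = True

    def __post_init__(self):
        self.image_size = tuple(int(v) for v in self.image_size)
        if self.fv % self.n_heads != 0:
            raise ValueError(f"fv={self.fv} must be divisible by n_heads={self.n_heads}")
        if self.fp % 4 != 0:
            raise ValueError(f"fp={self.fp} must be a multiple of 4")
        div = 2**self.depth
        h, w = self.image_size
        if h % div or w % div:
            raise ValueError(
                f"image size {self.image_size} must be divisible by 2**depth = {div}"
            )

    @property
    def bottleneck_channels(self) -> int:
        return self.f0 * 2**self.depth


def fourier_pos_embedding(h: int, w: int, fp: int) -> np.ndarray:
    """2D Fourier positional embedding of width ``fp`` for an h x w grid.

    For pixel (i, j) with coordinates normalized to [0, 1) — half-open so
    that the periodic basis never aliases the two grid edges onto the
    same embedding — the embedding stacks [sin(2 pi s_k i),
    cos(2 pi s_k i), sin(2 pi s_k j), cos(2 pi s_k j)] over fp/4
    geometric frequencies s_k in {1, 2, 4, ...}.  Returns an (h*w, fp)
    array in row-major token order.
    """
    if fp % 4 != 0:
        raise ValueError("fp must be a multiple of 4")
    if fp == 0:
        return np.zeros((h * w, 0))
    ii, jj = np.mgrid[0:h, 0:w].astype(np.float64)
    ii = ii / h
    jj = jj / w
    out = np.empty((h, w, fp))
    for k in range(fp // 4):
        s = 2.0**k
        out[..., 4 * k + 0] = np.sin(2 * np.pi * s * ii)
        out[..., 4 * k + 1] = np.cos(2 * np.pi * s * ii)
        out[..., 4 * k + 2] = np.sin(2 * np.pi * s * jj)
        out[..., 4 * k + 3] = np.cos(2 * np.pi * s * jj)
    return out.reshape(h * w, fp)


class CBAM(Module):
    """Convolutional block attention: channel gate then spatial gate."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 8):
        hidden = max(channels // reduction, 1)
        self.mlp_in = Linear(channels, hidden, rng)
        self.mlp_out = Linear(hidden, channels, rng)
        self.spatial_conv = Conv2d(2, 1, 7, rng, stride=1, padding=3)
        self.channels = channels

    def _shared_mlp(self, pooled: Tensor) -> Tensor:
        return self.mlp_out(self.mlp_in(pooled).relu())

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        avg = x.mean(axis=(2, 3))  # (N, C)
        mx = x.max(axis=3).max(axis=2)  # (N, C)
        gate_c = (self._shared_mlp(avg) + self._shared_mlp(mx)).sigmoid()
        x = x * gate_c.reshape(n, c, 1, 1)
        ch_mean = x.mean(axis=1, keepdims=True)
        ch_max = x.max(axis=1, keepdims=True)
        gate_s = self.spatial_conv(concat([ch_mean, ch_max], axis=1)).sigmoid()
        return x * gate_s


class _Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class _ConvBlock(Module):
    """conv -> instance norm -> ReLU (-> CBAM)."""

    def __init__(self, cin, cout, k, rng, stride, padding, cbam: bool, reduction: int):
        self.conv = Conv2d(cin, cout, k, rng, stride=stride, padding=padding)
        self.norm = InstanceNorm2d(cout)
        self.cbam = CBAM(cout, rng, reduction) if cbam else _Identity()

    def forward(self, x: Tensor) -> Tensor:
        return self.cbam(self.norm(self.conv(x)).relu())


class _RezeroBlock(Module):
    """Pre-norm transformer encoder block with rezero residual scaling."""

    def __init__(self, fv: int, n_heads: int, mlp_ratio: int, alpha_init: float, rng):
        self.n_heads = n_heads
        self.head_dim = fv // n_heads
        self.ln_attn = LayerNorm(fv)
        self.ln_mlp = LayerNorm(fv)
        self.q = Linear(fv, fv, rng)
        self.k = Linear(fv, fv, rng)
        self.v = Linear(fv, fv, rng)
        self.attn_out = Linear(fv, fv, rng)
        self.mlp_in = Linear(fv, fv * mlp_ratio, rng)
        self.mlp_out = Linear(fv * mlp_ratio, fv, rng)
        self.alpha_attn = Parameter(np.full((), alpha_init, dtype=np.float64))
        self.alpha_mlp = Parameter(np.full((), alpha_init, dtype=np.float64))

    def _attention(self, t: Tensor) -> Tensor:
        n, seq, fv = t.shape
        h, d = self.n_heads, self.head_dim

        def heads(x):  # (N, T, fv) -> (N, h, T, d)
            return x.reshape(n, seq, h, d).transpose((0, 2, 1, 3))

        q, k, v = heads(self.q(t)), heads(self.k(t)), heads(self.v(t))
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(d))
        attn = softmax_last(scores)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape(n, seq, fv)
        return self.attn_out(out)

    def forward(self, t: Tensor) -> Tensor:
        t = t + self.alpha_attn * self._attention(self.ln_attn(t))
        t = t + self.alpha_mlp * self.mlp_out(self.mlp_in(self.ln_mlp(t)).relu())
        return t


class VitBottleneck(Module):
    """Token-sequence transformer over the coarsest U-net feature grid.

    Flattens (N, f, h, w) to h*w tokens of width f, concatenates the
    fp-dimensional Fourier positional embedding, projects to width fv,
    applies ``vit_blocks`` rezero encoder blocks, projects back to f and
    unflattens.  Output shape equals input shape.
    """

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        f = cfg.bottleneck_channels
        self.cfg = cfg
        self.in_proj = Linear(f + cfg.fp, cfg.fv, rng)
        self.blocks = [
            _RezeroBlock(cfg.fv, cfg.n_heads, cfg.mlp_ratio, cfg.alpha_init, rng)
            for _ in range(cfg.vit_blocks)
        ]
        self.out_proj = Linear(cfg.fv, f, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, f, h, w = x.shape
        tokens = x.reshape(n, f, h * w).transpose((0, 2, 1))  # (N, T, f)
        if self.cfg.fp > 0:
            pos = fourier_pos_embedding(h, w, self.cfg.fp)
            pos = Tensor(np.broadcast_to(pos, (n,) + pos.shape).copy())
            tokens = concat([tokens, pos], axis=2)
        t = self.in_proj(tokens)
        for block in self.blocks:
            t = block(t)
        out = self.out_proj(t)
        return out.transpose((0, 2, 1)).reshape(n, f, h, w)


class Generator(Module):
    """The full translation generator: encode -> ViT bottleneck -> decode."""

    def __init__(self, cfg: GeneratorConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        f0, depth = cfg.f0, cfg.depth
        self.pre = _ConvBlock(cfg.in_channels, f0, 7, rng, stride=1, padding=3,
                              cbam=False, reduction=cfg.cbam_reduction)
        self.down = [
            _ConvBlock(f0 * 2**k, f0 * 2 ** (k + 1), 3, rng, stride=2, padding=1,
                       cbam=cfg.use_cbam, reduction=cfg.cbam_reduction)
            for k in range(depth)
        ]
        self.vit = VitBottleneck(cfg, rng) if cfg.use_vit else _Identity()
        self.up = []
        self.post_skip = []
        for k in range(depth, 0, -1):
            cin, cout = f0 * 2**k, f0 * 2 ** (k - 1)
            self.up.append(
                ConvTranspose2d(cin, cout, 3, rng, stride=2, padding=1, output_padding=1)
            )
            self.post_skip.append(
                _ConvBlock(2 * cout, cout, 3, rng, stride=1, padding=1,
                           cbam=cfg.use_cbam, reduction=cfg.cbam_reduction)
            )
        self.up_norms = [InstanceNorm2d(f0 * 2 ** (k - 1)) for k in range(depth, 0, -1)]
        self.final = Conv2d(f0, cfg.out_channels, 7, rng, stride=1, padding=3)

    # -- pieces ------------------------------------------------------------
    def _check_size(self, x: Tensor):
        div = 2**self.cfg.depth
        h, w = x.shape[2], x.shape[3]
        if h % div or w % div:
            raise ValueError(
                f"input spatial size {h}x{w} must be divisible by 2**depth = {div} "
                f"(depth={self.cfg.depth})"
            )

    def encode(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Returns (bottleneck, skips); skip k is the pre-downsample feature
        grid at level k (spatial H/2^k, channels f0*2^k for k=0..depth-1)."""
        x = self._as_tensor(x)
        self._check_size(x)
        feat = self.pre(x)
        skips = []
        for block in self.down:
            skips.append(feat)
            feat = block(feat)
        return feat, skips

    def bottleneck(self, feat: Tensor) -> Tensor:
        return self.vit(feat)

    def decode(self, feat: Tensor, skips: list[Tensor]) -> Tensor:
        if len(skips) != self.cfg.depth:
            raise ValueError(f"expected {self.cfg.depth} skip tensors, got {len(skips)}")
        for i, (upconv, norm, post) in enumerate(zip(self.up, self.up_norms, self.post_skip)):
            skip = skips[-(i + 1)]
            feat = norm(upconv(feat)).relu()
            if feat.shape != skip.shape:
                raise ValueError(
                    f"skip/bottleneck shape mismatch at level {self.cfg.depth - i}: "
                    f"decoder produced {feat.shape}, skip has {skip.shape}"
                )
            feat = post(concat([feat, skip], axis=1))
        return self.final(feat).tanh()

    def forward(self, x) -> Tensor:
        feat, skips = self.encode(x)
        feat = self.bottleneck(feat)
        return self.decode(feat, skips)

    @staticmethod
    def _as_tensor(x) -> Tensor:
        if isinstance(x, Tensor):
            t = x
        else:
            t = Tensor(np.asarray(x, dtype=np.float64))
        if t.ndim == 2:
            t = t.reshape(1, 1, *t.shape)
        if t.ndim != 4:
            raise ValueError(f"expected (H,W) or (N,C,H,W) input, got shape {t.shape}")
        return t


def parameter_breakdown(gen: Generator) -> dict[str, int]:
    """Parameter counts per architectural component (pure function of the
    config and toggles; useful for checking ablation deltas)."""
    groups = {"pre": 0, "encoder": 0, "vit": 0, "decoder": 0, "cbam": 0, "final": 0}
    for name, p in gen.named_parameters():
        if ".cbam." in name:
            groups["cbam"] += p.data.size
        elif name.startswith("pre"):
            groups["pre"] += p.data.size
        elif name.startswith("down"):
            groups["encoder"] += p.data.size
        elif name.startswith("vit"):
            groups["vit"] += p.data.size
        elif name.startswith(("up", "post_skip")):
            groups["decoder"] += p.data.size
        elif name.startswith("final"):
            groups["final"] += p.data.size
    groups["total"] = gen.n_parameters
    return groups
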
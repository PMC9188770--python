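"""Conditional-GAN image-to-segmentation translation.

The translator is a UNet generator trained adversarially against a
PatchGAN discriminator: the generator maps a beach photograph to the
*segmented-image domain* (the palette-colored rendering of the mask),
and the discriminator scores (source, candidate-target) pairs patch by
patch, producing a 2-D grid of real/fake logits. The generator loss is
``adversarial_weight * BCE(fake scores, 1) + l1_weight * mean|fake - target|``;
with ``adversarial_weight = 0`` it reduces to pure L1 regression. The
network's only source of randomness at prediction time is dropout, which
can be left active at inference (``inference_dropout``).

Masks travel through the network as palette RGB scaled to [-1, 1], not
one-hot — translation targets the colored segmented image, and the
continuous output is hardened into labels downstream by k-means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    LeakyReLU,
    Mode,
    Param,
    ReLU,
    Sequential,
    Tanh,
    bce_with_logits,
    conv_out_size,
    l1_loss,
)
from .io_dataset import ImagePair

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "TrainConfig",
    "UNetGenerator",
    "PatchDiscriminator",
    "build_generator",
    "build_discriminator",
    "generator_loss",
    "discriminator_loss",
    "train",
    "translate",
    "TrainResult",
    "desk_scale_specs",
    "save_generator",
    "load_generator",
    "rgb_to_net",
    "net_to_rgb",
]

F32 = np.float32


@dataclass
class GeneratorSpec:
    """UNet generator architecture.

    The encoder halves the spatial size once per block until the
    bottleneck reaches 1x1, so ``len(encoder_filters)`` must equal
    ``log2(input_size)``. The first encoder block omits batch
    normalization by default (``first_block_batchnorm`` restores it);
    decoder blocks are transposed convolutions with batch norm, ReLU,
    and dropout on the first ``dropout_blocks`` blocks. A final
    stride-1 convolution maps to 3 channels through tanh.
    """

    encoder_filters: tuple[int, ...] = (64, 128, 256, 512, 512, 512, 512, 512)
    decoder_filters: tuple[int, ...] = (512, 512, 512, 512, 256, 128, 64, 64)
    dropout_blocks: int = 3
    dropout_p: float = 0.5
    init_mean: float = 0.0
    init_sd: float = 0.02
    input_size: int = 256
    first_block_batchnorm: bool = False

    def __post_init__(self) -> None:
        d = len(self.encoder_filters)
        if len(self.decoder_filters) != d:
            raise ValueError("encoder and decoder must have equal depth")
        if 2**d != self.input_size:
            raise ValueError(
                f"depth {d} incompatible with input_size {self.input_size}: "
                f"need 2^depth == input_size so the bottleneck reaches 1x1"
            )
        if not 0.0 <= self.dropout_p <= 1.0:
            raise ValueError("dropout_p outside [0, 1]")
        if self.dropout_blocks > d:
            raise ValueError("dropout_blocks exceeds decoder depth")


@dataclass
class DiscriminatorSpec:
    """PatchGAN discriminator: all blocks stride 2 except the last
    (stride 1), then a stride-1 single-channel head of patch logits."""

    filters: tuple[int, ...] = (64, 128, 256, 512)
    init_mean: float = 0.0
    init_sd: float = 0.02

    def __post_init__(self) -> None:
        if len(self.filters) < 1:
            raise ValueError("need at least one discriminator block")


@dataclass
class TrainConfig:
    epochs: int = 25
    batch_size: int = 8
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    l1_weight: float = 100.0
    adversarial_weight: float = 1.0
    seed: int = 0
    inference_dropout: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0 or self.adam_beta1 <= 0:
            raise ValueError("optimizer scalars must be positive")
        if self.l1_weight < 0 or self.adversarial_weight < 0:
            raise ValueError("loss weights must be non-negative")


# ---------------------------------------------------------------------------
# models


class UNetGenerator:
    """Encoder-decoder with skip connections; see :class:`GeneratorSpec`."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        init = (spec.init_mean, spec.init_sd, rng)
        d = len(spec.encoder_filters)
        self.enc: list[Sequential] = []
        cin = 3
        for i, f in enumerate(spec.encoder_filters):
            layers: list = [Conv2d(cin, f, 4, 2, 1, init=init)]
            # batch statistics at the 1x1 bottleneck are degenerate -> no BN
            use_bn = (i > 0 or spec.first_block_batchnorm) and i < d - 1
            if use_bn:
                layers.append(BatchNorm2d(f, init=init))
            layers.append(LeakyReLU(0.2))
            self.enc.append(Sequential(*layers))
            cin = f
        self.dec: list[Sequential] = []
        for i, f in enumerate(spec.decoder_filters):
            if i == 0:
                cin = spec.encoder_filters[-1]
            else:
                cin = spec.decoder_filters[i - 1] + spec.encoder_filters[d - 1 - i]
            layers = [ConvTranspose2d(cin, f, 4, 2, 1, init=init), BatchNorm2d(f, init=init)]
            if i < spec.dropout_blocks:
                layers.append(Dropout(spec.dropout_p))
            layers.append(ReLU())
            self.dec.append(Sequential(*layers))
        self.final = Sequential(
            Conv2d(spec.decoder_filters[-1], 3, 3, 1, 1, init=init), Tanh()
        )

    # -- plumbing ----------------------------------------------------------
    def _blocks(self):
        return [*self.enc, *self.dec, self.final]

    def params(self) -> list[Param]:
        return [p for b in self._blocks() for p in b.params()]

    def forward(self, x: np.ndarray, mode: Mode):
        d = len(self.enc)
        skips, ecaches = [], []
        h = np.ascontiguousarray(x, dtype=F32)
        for blk in self.enc:
            h, c = blk.forward(h, mode)
            skips.append(h)
            ecaches.append(c)
        dcaches = []
        h = skips[-1]
        for i, blk in enumerate(self.dec):
            if i > 0:
                h = np.concatenate([h, skips[d - 1 - i]], axis=1)
            h, c = blk.forward(h, mode)
            dcaches.append(c)
        y, fcache = self.final.forward(h, mode)
        return y, (ecaches, dcaches, fcache)

    def backward(self, dy: np.ndarray, cache) -> np.ndarray:
        ecaches, dcaches, fcache = cache
        d = len(self.enc)
        dskip = [None] * (d + 1)  # 1-based: grads w.r.t. encoder outputs e_1..e_d
        g = self.final.backward(dy, fcache)
        for i in range(d - 1, -1, -1):
            g = self.dec[i].backward(g, dcaches[i])
            if i > 0:
                ch = self.spec.decoder_filters[i - 1]
                g, gskip = g[:, :ch], g[:, ch:]
                j = d - i  # skip was e_{d-i}
                dskip[j] = gskip if dskip[j] is None else dskip[j] + gskip
            else:
                dskip[d] = g if dskip[d] is None else dskip[d] + g
        g = dskip[d]
        for j in range(d, 0, -1):
            g = self.enc[j - 1].backward(g, ecaches[j - 1])
            if j > 1 and dskip[j - 1] is not None:
                g = g + dskip[j - 1]
        return g


class PatchDiscriminator:
    """Markovian discriminator over (source, target) channel concatenations."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        init = (spec.init_mean, spec.init_sd, rng)
        layers: list = []
        cin = 6
        n = len(spec.filters)
        for i, f in enumerate(spec.filters):
            stride = 2 if i < n - 1 else 1
            layers.append(Conv2d(cin, f, 4, stride, 1, init=init))
            if i > 0:
                layers.append(BatchNorm2d(f, init=init))
            layers.append(LeakyReLU(0.2))
            cin = f
        layers.append(Conv2d(cin, 1, 4, 1, 1, init=init))
        self.net = Sequential(*layers)

    def params(self) -> list[Param]:
        return self.net.params()

    def score_grid_size(self, input_size: int) -> int:
        size = input_size
        n = len(self.spec.filters)
        for i in range(n):
            size = conv_out_size(size, 4, 2 if i < n - 1 else 1, 1)
        return conv_out_size(size, 4, 1, 1)

    def forward(self, source: np.ndarray, target: np.ndarray, mode: Mode):
        if source.shape != target.shape:
            raise ValueError(
                f"source {source.shape} and target {target.shape} shapes differ"
            )
        x = np.concatenate(
            [np.asarray(source, dtype=F32), np.asarray(target, dtype=F32)], axis=1
        )
        return self.net.forward(x, mode)

    def backward(self, dy: np.ndarray, cache) -> tuple[np.ndarray, np.ndarray]:
        """Returns gradients w.r.t. (source, target)."""
        g = self.net.backward(dy, cache)
        return g[:, :3], g[:, 3:]


def build_generator(spec: GeneratorSpec, seed: int = 0) -> UNetGenerator:
    """Construct a freshly initialized UNet generator (weights ~ Normal)."""
    return UNetGenerator(spec, seed=seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(spec, seed=seed)


# ---------------------------------------------------------------------------
# losses


def generator_loss(
    fake_scores: np.ndarray,
    fake_image: np.ndarray,
    target_image: np.ndarray,
    cfg: TrainConfig,
) -> float:
    """``adversarial_weight * BCE(scores, 1) + l1_weight * mean|fake - target|``.

    Scores are patch logits. With ``adversarial_weight = 0`` this is the
    plain mean-absolute-error between translation and target.
    """
    if np.shape(fake_image) != np.shape(target_image):
        raise ValueError("fake and target image shapes differ")
    adv = bce_with_logits(fake_scores, 1.0)[0] if cfg.adversarial_weight else 0.0
    l1 = l1_loss(fake_image, target_image)[0]
    return cfg.adversarial_weight * adv + cfg.l1_weight * l1


def discriminator_loss(real_scores: np.ndarray, fake_scores: np.ndarray) -> float:
    """``BCE(real scores, 1) + BCE(fake scores, 0)`` over patch logits."""
    if np.shape(real_scores) != np.shape(fake_scores):
        raise ValueError("real and fake score shapes differ")
    return bce_with_logits(real_scores, 1.0)[0] + bce_with_logits(fake_scores, 0.0)[0]


# ---------------------------------------------------------------------------
# data conversion


def rgb_to_net(rgb: np.ndarray) -> np.ndarray:
    """(H, W, 3) uint8 -> (3, H, W) float32 in [-1, 1]."""
    return (np.asarray(rgb, dtype=F32).transpose(2, 0, 1) / F32(127.5)) - F32(1.0)


def net_to_rgb(x: np.ndarray) -> np.ndarray:
    """(3, H, W) float in [-1, 1] -> (H, W, 3) uint8."""
    y = (np.asarray(x, dtype=np.float64).transpose(1, 2, 0) + 1.0) * 127.5
    return np.clip(np.round(y), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainResult:
    generator: UNetGenerator
    discriminator: PatchDiscriminator
    history: list[dict[str, float]]  # per-epoch: gen_loss, disc_loss, l1


def train(
    pairs: list[ImagePair],
    gen_spec: GeneratorSpec,
    disc_spec: DiscriminatorSpec,
    cfg: TrainConfig,
) -> TrainResult:
    """Adversarial training: alternating discriminator/generator updates.

    Masks enter the network as their palette-color RGB renderings scaled
    to [-1, 1]. Deterministic for a fixed ``cfg.seed`` (weight init,
    batch order, and dropout all derive from it).
    """
    if not pairs:
        raise ValueError("empty dataset")
    size = pairs[0].rgb.shape[0]
    if any(p.rgb.shape != pairs[0].rgb.shape for p in pairs):
        raise ValueError("all pairs must share dimensions")
    if size != gen_spec.input_size or pairs[0].rgb.shape[1] != gen_spec.input_size:
        raise ValueError(
            f"pairs are {pairs[0].rgb.shape[:2]} but generator expects "
            f"{gen_spec.input_size}x{gen_spec.input_size}"
        )

    ss = np.random.SeedSequence(cfg.seed)
    s_init_g, s_init_d, s_loop = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    gen = build_generator(gen_spec, seed=s_init_g)
    disc = build_discriminator(disc_spec, seed=s_init_d)
    rng = np.random.default_rng(s_loop)
    mode = Mode(batch_stats=True, dropout=True, rng=rng)

    opt_g = Adam(gen.params(), lr=cfg.learning_rate, beta1=cfg.adam_beta1)
    opt_d = Adam(disc.params(), lr=cfg.learning_rate, beta1=cfg.adam_beta1)

    x_all = np.stack([rgb_to_net(p.rgb) for p in pairs])
    y_all = np.stack([rgb_to_net(p.mask.to_rgb()) for p in pairs])
    n = len(pairs)
    history: list[dict[str, float]] = []
    use_adv = cfg.adversarial_weight > 0

    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        g_sum = d_sum = l1_sum = 0.0
        nb = 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            x, y = x_all[idx], y_all[idx]
            fake, gcache = gen.forward(x, mode)

            d_loss = 0.0
            if use_adv:
                # discriminator update (generator output detached)
                opt_d.zero_grad()
                zr, cr = disc.forward(x, y, mode)
                lr_, gr = bce_with_logits(zr, 1.0)
                disc.backward(gr, cr)
                zf, cf = disc.forward(x, fake, mode)
                lf_, gf = bce_with_logits(zf, 0.0)
                disc.backward(gf, cf)
                opt_d.step()
                d_loss = lr_ + lf_

            # generator update
            opt_g.zero_grad()
            l1, dl1 = l1_loss(fake, y)
            dfake = cfg.l1_weight * dl1
            adv = 0.0
            if use_adv:
                zf2, cf2 = disc.forward(x, fake, mode)
                adv, gz = bce_with_logits(zf2, 1.0)
                for p in disc.params():  # scores flow through D; D stays fixed
                    p.grad[...] = 0.0
                _, dtgt = disc.backward(gz, cf2)
                for p in disc.params():
                    p.grad[...] = 0.0
                dfake = dfake + cfg.adversarial_weight * dtgt
            gen.backward(dfake.astype(F32), gcache)
            opt_g.step()

            g_sum += cfg.adversarial_weight * adv + cfg.l1_weight * l1
            d_sum += d_loss
            l1_sum += l1
            nb += 1
        history.append(
            {
                "epoch": epoch + 1,
                "gen_loss": g_sum / nb,
                "disc_loss": d_sum / nb,
                "l1": l1_sum / nb,
            }
        )
    return TrainResult(generator=gen, discriminator=disc, history=history)


def translate(
    generator: UNetGenerator,
    rgb: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Translate a photograph into the segmented-image domain.

    Returns the continuous generator output rescaled to 8-bit RGB.
    Dropout is active iff ``cfg.inference_dropout``; with it off the
    output is deterministic.
    """
    rgb = np.asarray(rgb)
    if rgb.shape[:2] != (generator.spec.input_size, generator.spec.input_size):
        raise ValueError(
            f"input {rgb.shape[:2]} does not match generator size "
            f"{generator.spec.input_size}"
        )
    mode = Mode(
        batch_stats=False,
        dropout=cfg.inference_dropout,
        rng=rng if rng is not None else np.random.default_rng(),
    )
    out, _ = generator.forward(rgb_to_net(rgb)[None], mode)
    return net_to_rgb(out[0])


# ---------------------------------------------------------------------------
# presets & checkpoints


def desk_scale_specs(
    input_size: int = 64, base: int = 16
) -> tuple[GeneratorSpec, DiscriminatorSpec]:
    """Reduced-width architecture for CPU-scale synthetic experiments.

    Depth still satisfies 2^depth = input_size; widths grow from ``base``
    and saturate at ``4 * base`` (the full-scale architecture uses base
    64 saturating at 512).
    """
    d = int(np.log2(input_size))
    if 2**d != input_size:
        raise ValueError("input_size must be a power of two")
    enc = tuple(min(base * 2**i, base * 4) for i in range(d))
    dec = tuple(reversed(enc))
    # patch discriminator needs >= 5 px after its stride-2 stack
    n_disc = max(1, min(4, d - 2))
    disc = tuple(base * 2**i for i in range(n_disc))
    return (
        GeneratorSpec(encoder_filters=enc, decoder_filters=dec, input_size=input_size),
        DiscriminatorSpec(filters=disc),
    )


def _state_arrays(gen: UNetGenerator) -> dict[str, np.ndarray]:
    arrays: dict[str, np.ndarray] = {}
    i = 0
    for blk in gen._blocks():
        for layer in blk.layers:
            for p in layer.params():
                arrays[f"p{i:04d}"] = p.value
                i += 1
            if isinstance(layer, BatchNorm2d):
                arrays[f"p{i:04d}"] = layer.running_mean
                i += 1
                arrays[f"p{i:04d}"] = layer.running_var
                i += 1
    return arrays


def save_generator(gen: UNetGenerator, path: Path | str) -> Path:
    """Checkpoint generator weights + batch-norm running stats (.npz)."""
    path = Path(path)
    spec_json = json.dumps(
        {
            "encoder_filters": list(gen.spec.encoder_filters),
            "decoder_filters": list(gen.spec.decoder_filters),
            "dropout_blocks": gen.spec.dropout_blocks,
            "dropout_p": gen.spec.dropout_p,
            "init_mean": gen.spec.init_mean,
            "init_sd": gen.spec.init_sd,
            "input_size": gen.spec.input_size,
            "first_block_batchnorm": gen.spec.first_block_batchnorm,
        }
    )
    np.savez(path, spec=np.array(spec_json), **_state_arrays(gen))
    return path


def load_generator(path: Path | str) -> UNetGenerator:
    with np.load(path) as data:
        cfg = json.loads(str(data["spec"]))
        cfg["encoder_filters"] = tuple(cfg["encoder_filters"])
        cfg["decoder_filters"] = tuple(cfg["decoder_filters"])
        gen = UNetGenerator(GeneratorSpec(**cfg), seed=0)
        i = 0
        for blk in gen._blocks():
            for layer in blk.layers:
                for p in layer.params():
                    p.value = data[f"p{i:04d}"].astype(F32)
                    p.grad = np.zeros_like(p.value)
                    i += 1
                if isinstance(layer, BatchNorm2d):
                    layer.running_mean = data[f"p{i:04d}"].astype(F32)
                    i += 1
                    layer.running_var = data[f"p{i:04d}"].astype(F32)
                    i += 1
    return gen
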
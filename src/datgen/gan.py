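"""Conditional GAN for early-to-delayed PET translation.

Generator: 2D multi-slice U-Net (encoder-decoder with skip connections,
instance normalization, LeakyReLU 0.2, tanh output); conditioned on the 75
early-phase channels it emits the central delayed-phase slice in [-1, 1].
Dropout (rate 0.5) is applied at decoder levels whose feature maps are
smaller than 64 x 64, and only during training so inference is
deterministic.

Discriminator: patch-based convolutional classifier scoring the
(condition stack, delayed slice) pair; its score map is judged with binary
cross-entropy on logits (least-squares variant available by flag).

Total objective:  L_total = lambda_GAN * L_GAN + lambda_L1 * L_L1
with lambda_GAN = 1.0 and lambda_L1 = 100.0; Adam (lr 2e-4, beta1 0.5),
batch size one.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import affine_transform

from . import nn
from .preprocess import (PreparedStudy, TrainingSample, inverse_scale_delayed,
                         stack_for_slice)


@dataclass(frozen=True)
class GeneratorConfig:
    in_channels: int = 75
    base_filters: int = 64
    depth: int = 4
    dropout_rate: float = 0.5
    leaky_slope: float = 0.2
    #: dropout applies at decoder levels with spatial dims below this
    dropout_below: int = 64

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")


@dataclass(frozen=True)
class DiscriminatorConfig:
    in_channels: int = 76  # generator in_channels + 1 (the judged slice)
    n_layers: int = 3
    base_filters: int = 64


@dataclass(frozen=True)
class LossWeights:
    lambda_gan: float = 1.0
    lambda_l1: float = 100.0

    def __post_init__(self):
        if self.lambda_gan < 0 or self.lambda_l1 < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class AugmentConfig:
    rotation_deg: float = 10.0
    shear_deg: float = 5.0
    scale_range: tuple[float, float] = (0.95, 1.05)


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    epochs: int = 200
    seed: int = 0
    augment: bool = True
    aug: AugmentConfig = field(default_factory=AugmentConfig)
    lsgan: bool = False


# ----------------------------------------------------------------------------
# Networks
# ----------------------------------------------------------------------------

class Generator:
    """U-Net with ``depth`` stride-2 encoder levels and mirrored decoder.

    Encoder level i maps to base_filters * 2^i channels (capped at 8x);
    decoder levels upsample with transposed convolutions and concatenate the
    mirrored encoder activation (skip connection) before the next level.
    Instance norm is omitted on the first encoder layer, per convention.
    """

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        self.cfg = cfg
        b = cfg.base_filters
        mult = [min(2 ** i, 8) for i in range(cfg.depth)]
        self.enc: list[list[nn.Layer]] = []
        cin = cfg.in_channels
        for i, m in enumerate(mult):
            block: list[nn.Layer] = [nn.Conv2d(cin, b * m, rng=rng)]
            if i > 0:
                block.append(nn.InstanceNorm(b * m))
            block.append(nn.LeakyReLU(cfg.leaky_slope))
            self.enc.append(block)
            cin = b * m
        self.dec: list[list[nn.Layer]] = []
        self._dec_out: list[int] = []
        for i in reversed(range(cfg.depth - 1)):
            cout = b * mult[i]
            block = [nn.ConvTranspose2d(cin, cout, rng=rng),
                     nn.InstanceNorm(cout),
                     nn.Dropout(cfg.dropout_rate, rng),
                     nn.LeakyReLU(cfg.leaky_slope)]
            self.dec.append(block)
            self._dec_out.append(cout)
            cin = cout + b * mult[i]  # after skip concatenation
        self.final = nn.ConvTranspose2d(cin, 1, rng=rng)
        self.tanh = nn.Tanh()

    def params(self) -> list[nn.Param]:
        ps = [p for blk in self.enc + self.dec for l in blk for p in l.params()]
        return ps + self.final.params()

    def _check(self, x: np.ndarray):
        h, w = x.shape[-2:]
        d = 2 ** self.cfg.depth
        if h % d or w % d:
            raise ValueError(f"spatial dims {h}x{w} not divisible by 2^depth={d}")
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} channels, got {x.shape[1]}")

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._check(x)
        skips = []
        for blk in self.enc:
            for l in blk:
                x = l.forward(x, train)
            skips.append(x)
        self._skip_channels = []
        for i, blk in enumerate(self.dec):
            for l in blk:
                use_train = train
                if isinstance(l, nn.Dropout) and min(x.shape[-2:]) >= self.cfg.dropout_below:
                    use_train = False  # feature map not smaller than 64x64
                x = l.forward(x, use_train)
            skip = skips[-(i + 2)]
            self._skip_channels.append((x.shape[1], skip.shape[1]))
            x = np.concatenate([x, skip], axis=1)
        x = self.final.forward(x, train)
        return self.tanh.forward(x, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.tanh.backward(grad)
        grad = self.final.backward(grad)
        skip_grads: list[np.ndarray | None] = [None] * len(self.enc)
        for i in reversed(range(len(self.dec))):
            c_dec, _ = self._skip_channels[i]
            gskip = grad[:, c_dec:]
            grad = grad[:, :c_dec]
            skip_grads[len(self.enc) - 2 - i] = gskip
            for l in reversed(self.dec[i]):
                grad = l.backward(grad)
        for i in reversed(range(len(self.enc))):
            if skip_grads[i] is not None and i != len(self.enc) - 1:
                grad = grad + skip_grads[i]
            for l in reversed(self.enc[i]):
                grad = l.backward(grad)
        return grad


class Discriminator:
    """PatchGAN-style classifier on the (condition, slice) channel stack."""

    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator):
        self.cfg = cfg
        b = cfg.base_filters
        layers: list[nn.Layer] = [nn.Conv2d(cfg.in_channels, b, rng=rng),
                                  nn.LeakyReLU(0.2)]
        cin = b
        for i in range(1, cfg.n_layers):
            cout = b * min(2 ** i, 8)
            stride = 2 if i < cfg.n_layers - 1 else 1
            layers += [nn.Conv2d(cin, cout, stride=stride, rng=rng),
                       nn.InstanceNorm(cout), nn.LeakyReLU(0.2)]
            cin = cout
        layers.append(nn.Conv2d(cin, 1, stride=1, rng=rng))
        self.net = nn.Sequential(*layers)

    def params(self):
        return self.net.params()

    def forward(self, cond: np.ndarray, slice_: np.ndarray, train=True) -> np.ndarray:
        x = np.concatenate([cond, slice_], axis=1)
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} channels, got {x.shape[1]}")
        return self.net.forward(x, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        """Returns the gradient w.r.t. the judged slice channel only."""
        g = self.net.backward(grad)
        return g[:, -1:]


def build_generator(cfg: GeneratorConfig, seed: int = 0) -> Generator:
    return Generator(cfg, np.random.default_rng(seed))


def build_discriminator(cfg: DiscriminatorConfig, seed: int = 0) -> Discriminator:
    return Discriminator(cfg, np.random.default_rng(seed))


# ----------------------------------------------------------------------------
# Losses
# ----------------------------------------------------------------------------

def l1_loss(generated: np.ndarray, real: np.ndarray) -> float:
    """Pixel-wise mean absolute error."""
    if generated.shape != real.shape:
        raise ValueError(f"shape mismatch {generated.shape} vs {real.shape}")
    return float(np.mean(np.abs(generated.astype(np.float64) - real)))


def gan_loss(disc_scores: np.ndarray, is_real: bool,
             lsgan: bool = False) -> float:
    """Adversarial loss of a discriminator score map against a label."""
    target = 1.0 if is_real else 0.0
    if lsgan:
        return float(np.mean((disc_scores.astype(np.float64) - target) ** 2))
    loss, _ = nn.bce_with_logits(disc_scores, target)
    return loss


def total_loss(gan: float, l1: float, w: LossWeights = LossWeights()) -> float:
    return w.lambda_gan * gan + w.lambda_l1 * l1


# ----------------------------------------------------------------------------
# Augmentation
# ----------------------------------------------------------------------------

def sample_augment_params(rng: np.random.Generator,
                          cfg: AugmentConfig = AugmentConfig()) -> dict:
    return {
        "rotation_deg": float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)),
        "shear_deg": float(rng.uniform(-cfg.shear_deg, cfg.shear_deg)),
        "scale": float(rng.uniform(*cfg.scale_range)),
    }


def _affine_matrix(params: dict, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    th = np.deg2rad(params["rotation_deg"])
    sh = np.tan(np.deg2rad(params["shear_deg"]))
    s = params["scale"]
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    shear = np.array([[1.0, sh], [0.0, 1.0]])
    m = (rot @ shear) / s
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - m @ center
    return m, offset


def apply_affine(plane: np.ndarray, params: dict) -> np.ndarray:
    m, off = _affine_matrix(params, *plane.shape)
    return affine_transform(plane.astype(np.float32), m, offset=off,
                            order=1, mode="nearest").astype(np.float32)


def augment(sample: TrainingSample, rng: np.random.Generator,
            cfg: AugmentConfig = AugmentConfig()) -> TrainingSample:
    """Apply one random rotation/shear/scale identically to every input
    channel and the target slice."""
    params = sample_augment_params(rng, cfg)
    if (params["rotation_deg"] == 0.0 and params["shear_deg"] == 0.0
            and params["scale"] == 1.0):
        return TrainingSample(sample.input_stack.copy(),
                              sample.target_slice.copy(), sample.slice_index)
    stack = np.stack([apply_affine(c, params) for c in sample.input_stack])
    target = apply_affine(sample.target_slice, params)
    return TrainingSample(stack, target, sample.slice_index)


# ----------------------------------------------------------------------------
# Training
# ----------------------------------------------------------------------------

@dataclass
class GanModel:
    generator: Generator
    discriminator: Discriminator
    gcfg: GeneratorConfig
    dcfg: DiscriminatorConfig
    weights: LossWeights
    history: dict[str, list[float]] = field(default_factory=dict)

    def save(self, path: str):
        os.makedirs(path, exist_ok=True)
        arrays = {f"g{i}": p.data for i, p in enumerate(self.generator.params())}
        arrays |= {f"d{i}": p.data for i, p in enumerate(self.discriminator.params())}
        np.savez(os.path.join(path, "weights.npz"), **arrays)
        with open(os.path.join(path, "config.json"), "w") as fh:
            json.dump({"generator": asdict(self.gcfg),
                       "discriminator": asdict(self.dcfg),
                       "weights": asdict(self.weights),
                       "history": self.history}, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "GanModel":
        with open(os.path.join(path, "config.json")) as fh:
            cfg = json.load(fh)
        gcfg = GeneratorConfig(**cfg["generator"])
        dcfg = DiscriminatorConfig(**cfg["discriminator"])
        model = cls(build_generator(gcfg), build_discriminator(dcfg), gcfg,
                    dcfg, LossWeights(**cfg["weights"]),
                    history=cfg.get("history", {}))
        with np.load(os.path.join(path, "weights.npz")) as npz:
            for i, p in enumerate(model.generator.params()):
                p.data[...] = npz[f"g{i}"]
            for i, p in enumerate(model.discriminator.params()):
                p.data[...] = npz[f"d{i}"]
        return model


def train(samples, gcfg: GeneratorConfig = GeneratorConfig(),
          dcfg: DiscriminatorConfig | None = None,
          w: LossWeights = LossWeights(),
          tcfg: TrainConfig = TrainConfig(),
          checkpoint_dir: str | None = None) -> GanModel:
    """Alternating per-sample discriminator/generator updates, batch size one.

    ``samples`` is any sequence of :class:`TrainingSample`.  The per-epoch
    history records mean L1, adversarial and total generator losses.  Fully
    deterministic for a fixed TrainConfig.seed under single-threaded BLAS.
    """
    n = len(samples)
    if n == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(tcfg.seed)
    dcfg = dcfg or DiscriminatorConfig(in_channels=gcfg.in_channels + 1,
                                       base_filters=gcfg.base_filters)
    gen = Generator(gcfg, rng)
    disc = Discriminator(dcfg, rng)
    opt_g = nn.Adam(gen.params(), lr=tcfg.lr, beta1=tcfg.beta1, beta2=tcfg.beta2)
    opt_d = nn.Adam(disc.params(), lr=tcfg.lr, beta1=tcfg.beta1, beta2=tcfg.beta2)
    history = {"l1": [], "gan": [], "total": [], "disc": []}

    for _epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        el1 = egan = edisc = 0.0
        for idx in order:
            s = samples[int(idx)]
            if tcfg.augment:
                s = augment(s, rng, tcfg.aug)
            x = s.input_stack[None]
            y = s.target_slice[None, None]

            fake = gen.forward(x, train=True)

            # --- discriminator update ---
            opt_d.zero_grad()
            sr = disc.forward(x, y, train=True)
            lr_, gr = _adv_grad(sr, 1.0, tcfg.lsgan)
            disc.backward(gr)
            sf = disc.forward(x, fake, train=True)
            lf, gf = _adv_grad(sf, 0.0, tcfg.lsgan)
            disc.backward(gf)
            for p in disc.params():
                p.grad *= 0.5
            opt_d.step()
            edisc += 0.5 * (lr_ + lf)

            # --- generator update ---
            opt_g.zero_grad()
            sf2 = disc.forward(x, fake, train=True)
            lg, gadv = _adv_grad(sf2, 1.0, tcfg.lsgan)
            grad_fake = w.lambda_gan * disc.backward(gadv)
            diff = fake.astype(np.float64) - y
            l1 = float(np.mean(np.abs(diff)))
            grad_fake = grad_fake + (w.lambda_l1 * np.sign(diff) / diff.size
                                     ).astype(np.float32)
            gen.backward(grad_fake)
            opt_g.step()
            el1 += l1
            egan += lg

        history["l1"].append(el1 / n)
        history["gan"].append(egan / n)
        history["total"].append(w.lambda_gan * egan / n + w.lambda_l1 * el1 / n)
        history["disc"].append(edisc / n)
        model = GanModel(gen, disc, gcfg, dcfg, w, history)
        if checkpoint_dir is not None:
            model.save(checkpoint_dir)
    return GanModel(gen, disc, gcfg, dcfg, w, history)


def _adv_grad(scores: np.ndarray, target: float, lsgan: bool):
    if lsgan:
        x = scores.astype(np.float64)
        return float(np.mean((x - target) ** 2)), \
            (2.0 * (x - target) / x.size).astype(np.float32)
    return nn.bce_with_logits(scores, target)


# ----------------------------------------------------------------------------
# Volumetric inference
# ----------------------------------------------------------------------------

def generate_volume(model: GanModel, prepared: PreparedStudy,
                    n_slices: int = 5) -> np.ndarray:
    """Slide the generator along the axial axis and rebuild the SUVR volume.

    One slice is predicted per slab slice; at the slab edges the conditioning
    stack is completed by replicating the outermost slices.  The tanh output
    is inverse-scaled to SUVR, so every voxel lies in (0, 10).
    """
    nz = prepared.early_channels.shape[1]
    out = []
    for z in range(nz):
        stack = stack_for_slice(prepared, z, n_slices, pad=True)
        if stack.shape[0] != model.gcfg.in_channels:
            raise ValueError(
                f"stack has {stack.shape[0]} channels, model expects "
                f"{model.gcfg.in_channels}")
        pred = model.generator.forward(stack[None], train=False)[0, 0]
        out.append(pred)
    return inverse_scale_delayed(np.stack(out, axis=0))
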
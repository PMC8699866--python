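"""DCGAN for spectrogram-image augmentation.

The generator maps a 100-dimensional latent vector through a dense
projection to an 8x8x512 tensor and four 5x5/stride-2 transposed
convolutions, halving channels and doubling the spatial size at each stage
up to a 128x128x3 Tanh output. The discriminator mirrors it with five
5x5/stride-2 convolutions (64 -> 1024 channels, Leaky ReLU slope 0.2) and a
sigmoid scalar. Batch normalization sits on every generator stage except
the output and on every discriminator convolution, not on the final scalar.
Training alternates generator and discriminator Adam updates
(lr 2e-4, beta1 0.5) on the cross-entropy adversarial loss; one GAN is
trained per class so generated images inherit a single class label.

Smaller image sizes for desk-scale experiments drop leading up-sampling
stages (a 32x32 generator starts from a 4x4 projection and uses three
stages) and may narrow ``base_channels`` while keeping the channel-halving
pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dense,
    Flatten,
    LeakyReLU,
    ReLU,
    Reshape,
    Sequential,
    Sigmoid,
    Tanh,
)
from .types import SpectrogramImage, stack_pixels

__all__ = [
    "GANConfig", "Generator", "Discriminator", "build_generator",
    "build_discriminator", "build_dcgan", "dcgan_loss", "train_dcgan",
    "generate_samples", "expand_dataset", "layer_output_shapes",
    "TrainingTrace",
]

_EPS = 1e-7


@dataclass
class GANConfig:
    """DCGAN hyperparameters (defaults follow the training recipe used at 128x128)."""

    latent_dim: int = 100
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    batch_size: int = 64
    epochs: int = 300
    leaky_slope: float = 0.2
    image_size: int = 128
    base_channels: int = 64
    generator_loss: str = "nonsaturating"  # or "minimax"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        size = self.image_size
        if size < 32 or (size & (size - 1)) != 0:
            raise ValueError("image_size must be a power of two >= 32")
        if self.generator_loss not in ("nonsaturating", "minimax"):
            raise ValueError("generator_loss must be 'nonsaturating' or 'minimax'")

    @property
    def start_size(self) -> int:
        """Spatial size of the dense projection (8 at full scale, 4 when scaled down)."""
        return 8 if self.image_size >= 64 else 4

    @property
    def n_stages(self) -> int:
        return int(np.log2(self.image_size // self.start_size))


@dataclass
class Generator:
    net: Sequential
    cfg: GANConfig

    def forward(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(z.astype(np.float32), train=train)


@dataclass
class Discriminator:
    net: Sequential
    cfg: GANConfig

    def forward(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(images.astype(np.float32), train=train)


def build_generator(cfg: GANConfig, rng: Optional[np.random.Generator] = None) -> Generator:
    rng = rng or np.random.default_rng(cfg.seed)
    s0 = cfg.start_size
    c0 = cfg.base_channels * 2 ** (cfg.n_stages - 1)
    layers = [
        Dense(cfg.latent_dim, s0 * s0 * c0, rng=rng, weight_scale=0.02),
        Reshape((c0, s0, s0)),
        BatchNorm2d(c0),
        ReLU(),
    ]
    ch = c0
    for stage in range(cfg.n_stages):
        out_ch = 3 if stage == cfg.n_stages - 1 else ch // 2
        layers.append(ConvTranspose2d(ch, out_ch, 5, 2, 2, rng=rng, weight_scale=0.02))
        if stage < cfg.n_stages - 1:
            layers += [BatchNorm2d(out_ch), ReLU()]
        ch = out_ch
    layers.append(Tanh())
    return Generator(Sequential(layers), cfg)


def build_discriminator(cfg: GANConfig, rng: Optional[np.random.Generator] = None) -> Discriminator:
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n_convs = int(np.log2(cfg.image_size // 4))
    layers: list = []
    ch_in = 3
    for stage in range(n_convs):
        ch_out = cfg.base_channels * 2**stage
        layers.append(Conv2d(ch_in, ch_out, 5, 2, 2, rng=rng, weight_scale=0.02))
        layers.append(BatchNorm2d(ch_out))
        layers.append(LeakyReLU(cfg.leaky_slope))
        ch_in = ch_out
    layers += [Flatten(), Dense(4 * 4 * ch_in, 1, rng=rng, weight_scale=0.02), Sigmoid()]
    return Discriminator(Sequential(layers), cfg)


def build_dcgan(cfg: GANConfig) -> Tuple[Generator, Discriminator]:
    rng = np.random.default_rng(cfg.seed)
    return build_generator(cfg, rng), build_discriminator(cfg, rng)


def layer_output_shapes(net: Sequential, x: np.ndarray) -> List[Tuple[int, ...]]:
    """Per-layer output shapes (excluding the batch axis) of a forward pass."""
    shapes = []
    for layer in net.layers:
        x = layer.forward(x, train=False)
        shapes.append(tuple(x.shape[1:]))
    return shapes


def _clamp(p: np.ndarray) -> np.ndarray:
    if np.any(p <= 0) or np.any(p >= 1):
        warnings.warn("discriminator probability at 0 or 1; clamping")
    return np.clip(p, _EPS, 1 - _EPS)


def dcgan_loss(d_real: np.ndarray, d_fake: np.ndarray,
               generator_loss: str = "nonsaturating") -> Tuple[float, float]:
    """Adversarial cross-entropy losses.

    ``loss_D = -[mean log D(x) + mean log(1 - D(G(z)))]``. The generator
    loss is the non-saturating ``-mean log D(G(z))`` by default, or the
    strict minimax ``mean log(1 - D(G(z)))``.
    """
    pr = _clamp(np.asarray(d_real, dtype=np.float64))
    pf = _clamp(np.asarray(d_fake, dtype=np.float64))
    loss_d = -(np.mean(np.log(pr)) + np.mean(np.log(1 - pf)))
    if generator_loss == "nonsaturating":
        loss_g = -np.mean(np.log(pf))
    elif generator_loss == "minimax":
        loss_g = np.mean(np.log(1 - pf))
    else:
        raise ValueError(f"unknown generator loss {generator_loss!r}")
    return float(loss_d), float(loss_g)


@dataclass
class TrainingTrace:
    epochs: List[int] = field(default_factory=list)
    loss_g: List[float] = field(default_factory=list)
    loss_d: List[float] = field(default_factory=list)

    def append(self, epoch: int, lg: float, ld: float) -> None:
        self.epochs.append(epoch)
        self.loss_g.append(lg)
        self.loss_d.append(ld)

    def __len__(self) -> int:
        return len(self.epochs)


def _images_to_tanh_batch(images: Sequence[SpectrogramImage]) -> np.ndarray:
    return (stack_pixels(images) * 2.0 - 1.0).astype(np.float32)


def train_dcgan(real_images: Sequence[SpectrogramImage], cfg: GANConfig,
                discriminator: Optional[Discriminator] = None,
                ) -> Tuple[Generator, TrainingTrace, Discriminator]:
    """Alternating adversarial training of one per-class DCGAN.

    Returns the trained generator, a per-epoch loss trace, and the
    discriminator (useful for equilibrium diagnostics). Fully deterministic
    for fixed data, config and seed in single-threaded BLAS.
    """
    n = len(real_images)
    if n < cfg.batch_size:
        raise ValueError(f"need at least one batch of {cfg.batch_size} real images, got {n}")
    x_real = _images_to_tanh_batch(real_images)
    if x_real.shape[2] != cfg.image_size:
        raise ValueError("image size mismatch between data and config")

    rng = np.random.default_rng(cfg.seed)
    gen = build_generator(cfg, np.random.default_rng(cfg.seed + 10))
    disc = discriminator or build_discriminator(cfg, np.random.default_rng(cfg.seed + 11))
    opt_g = Adam(gen.net, lr=cfg.learning_rate, beta1=cfg.adam_beta1)
    opt_d = Adam(disc.net, lr=cfg.learning_rate, beta1=cfg.adam_beta1)

    trace = TrainingTrace()
    bs = cfg.batch_size
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_lg, ep_ld, n_batches = 0.0, 0.0, 0
        for b0 in range(0, n - bs + 1, bs):
            idx = order[b0:b0 + bs]
            batch_real = x_real[idx]

            # (i) train G: fix D, push D(G(z)) toward "real". The forward pass
            # through D uses the same real+fake mixture as the D step so its
            # batch-norm statistics are consistent between the two steps.
            z = rng.standard_normal((bs, cfg.latent_dim)).astype(np.float32)
            fake = gen.net.forward(z, train=True)
            p_mix = disc.net.forward(np.concatenate([batch_real, fake]), train=True)
            pf = np.clip(p_mix[bs:], _EPS, 1 - _EPS)
            if cfg.generator_loss == "nonsaturating":
                dL_dp = -1.0 / (bs * pf)
            else:
                dL_dp = -1.0 / (bs * (1.0 - pf))
            dmix = np.zeros_like(p_mix)
            dmix[bs:] = dL_dp
            d_fake_in = disc.net.backward(dmix.astype(np.float32))[bs:]
            gen.net.backward(d_fake_in)
            opt_g.step()

            # (ii) train D: fix G, real -> 1, fake -> 0 (one combined batch so
            # batch-norm statistics reflect the mixture D is scored on)
            fake_detached = gen.net.forward(
                rng.standard_normal((bs, cfg.latent_dim)).astype(np.float32), train=True)
            batch_d = np.concatenate([batch_real, fake_detached])
            p_d = np.clip(disc.net.forward(batch_d, train=True), _EPS, 1 - _EPS)
            pr, pf2 = p_d[:bs], p_d[bs:]
            dL = np.concatenate([-1.0 / (bs * pr), 1.0 / (bs * (1.0 - pf2))])
            disc.net.backward(dL.astype(np.float32))
            opt_d.step()

            loss_d, loss_g = dcgan_loss(pr, pf2, cfg.generator_loss)
            if cfg.generator_loss == "nonsaturating":
                loss_g = float(-np.mean(np.log(pf)))
            ep_ld += loss_d
            ep_lg += loss_g
            n_batches += 1
        trace.append(epoch, ep_lg / n_batches, ep_ld / n_batches)
    return gen, trace, disc


def generate_samples(gen: Generator, n: int, seed: int,
                     class_label: Optional[str] = None) -> List[SpectrogramImage]:
    """Draw ``n`` images from the generator; Tanh output mapped to [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    out: List[SpectrogramImage] = []
    bs = max(1, min(64, n))
    made = 0
    while made < n:
        take = min(bs, n - made)
        z = rng.standard_normal((take, gen.cfg.latent_dim)).astype(np.float32)
        imgs = gen.net.forward(z, train=False)
        pixels = np.clip((imgs + 1.0) / 2.0, 0.0, 1.0)
        for j in range(take):
            out.append(SpectrogramImage(
                pixels[j].transpose(1, 2, 0), class_label=class_label,
                frame_ref=f"gan:{seed}:{made + j}", origin="gan_generated"))
        made += take
    return out


def expand_dataset(real: Sequence[SpectrogramImage], gen: Generator,
                   coefficient: int, seed: int = 0) -> List[SpectrogramImage]:
    """``coefficient`` generated images per real image of one class."""
    if coefficient < 0:
        raise ValueError("coefficient must be non-negative")
    if coefficient == 0:
        return []
    labels = {img.class_label for img in real}
    if len(labels) != 1:
        raise ValueError("expand_dataset expects a single-class real set")
    return generate_samples(gen, coefficient * len(real), seed, class_label=labels.pop())
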
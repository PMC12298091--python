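"""Toy-scale cycle-consistent image augmentation between IOP domains.

Two residual convolutional generators translate images between the
normal-pressure and high-pressure domains; two patch discriminators drive a
least-squares adversarial loss, and an L1 cycle-consistency term
||F(G(x)) - x|| keeps the translations reversible. The reference pipeline
uses this to synthesize 600 images per domain (1200 total) for backbone
pretraining.

No canonical architecture or schedule exists for this component at desk
scale; the defaults here (64 px, width <= 16 channels, a handful of
epochs) are deliberately small. A classic mode (flips, translations,
intensity jitter) provides a fast, training-free alternative so the
downstream stages can be exercised without adversarial training.

Identity generators (all conv weights zero, residual pass-through) give a
cycle loss of exactly zero -- a useful calibration point for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .nn import Adam, Conv2d, Module, Tensor

__all__ = [
    "CycleConfig",
    "AugmentedSet",
    "ResidualGenerator",
    "PatchDiscriminator",
    "train_cyclegan",
    "generate_augmented",
    "CycleGANAugmenter",
    "ClassicAugmenter",
]


@dataclass(frozen=True)
class CycleConfig:
    image_size: int = 64
    generator_width: int = 8
    discriminator_width: int = 8
    cycle_weight: float = 10.0
    epochs: int = 5
    learning_rate: float = 2e-3
    batch_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_weight < 0:
            raise ValueError("cycle_weight must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class AugmentedSet:
    """Generated images with domain labels and source provenance."""

    images: list[np.ndarray]
    domains: list[str]
    source_ids: list[int]

    def per_domain(self, domain: str) -> list[np.ndarray]:
        return [im for im, d in zip(self.images, self.domains) if d == domain]

    def __len__(self) -> int:
        return len(self.images)


class ResidualGenerator(Module):
    """x + conv stack, clipped to [0, 1]; zero weights give the identity."""

    def __init__(self, width: int, rng: np.random.Generator):
        self.c1 = Conv2d(1, width, 3, rng, padding=1)
        self.c2 = Conv2d(width, width, 3, rng, padding=1)
        self.c3 = Conv2d(width, 1, 3, rng, padding=1, scale=0.05)

    def forward(self, x: Tensor) -> Tensor:
        r = self.c2(self.c1(x).relu()).relu()
        return (x + self.c3(r)).clip(0.0, 1.0)

    def make_identity(self) -> "ResidualGenerator":
        for p in self.parameters():
            p.data[...] = 0.0
        return self

    def translate(self, images: np.ndarray) -> np.ndarray:
        """Apply to a stack of (N, H, W) images, returning the same shape."""
        x = Tensor(np.asarray(images, dtype=float)[:, None])
        return self.forward(x).data[:, 0]


class PatchDiscriminator(Module):
    def __init__(self, width: int, rng: np.random.Generator):
        self.c1 = Conv2d(1, width, 4, rng, stride=2, padding=1)
        self.c2 = Conv2d(width, 2 * width, 4, rng, stride=2, padding=1)
        self.c3 = Conv2d(2 * width, 1, 3, rng, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        return self.c3(self.c2(self.c1(x).leaky_relu()).leaky_relu())


def _l1(a: Tensor, b: Tensor) -> Tensor:
    return (a - b).abs().mean()


def train_cyclegan(
    images_normal: list[np.ndarray] | np.ndarray,
    images_high: list[np.ndarray] | np.ndarray,
    config: CycleConfig,
) -> tuple[ResidualGenerator, ResidualGenerator, list[dict[str, float]]]:
    """Train the two generators; returns (G_n2h, G_h2n, per-epoch history).

    Least-squares adversarial objectives plus weighted L1 cycle losses;
    deterministic given ``config.seed``. History entries carry the mean
    cycle, generator-adversarial and discriminator losses per epoch.
    """
    a = np.stack([np.asarray(i, dtype=float) for i in images_normal])
    b = np.stack([np.asarray(i, dtype=float) for i in images_high])
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both domains must be non-empty")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("domains must share an image size")
    rng = np.random.default_rng(config.seed)
    g_n2h = ResidualGenerator(config.generator_width, rng)
    g_h2n = ResidualGenerator(config.generator_width, rng)
    d_h = PatchDiscriminator(config.discriminator_width, rng)
    d_n = PatchDiscriminator(config.discriminator_width, rng)
    opt_g = Adam(g_n2h.parameters() + g_h2n.parameters(), lr=config.learning_rate)
    opt_d = Adam(d_h.parameters() + d_n.parameters(), lr=config.learning_rate)
    bs = config.batch_size
    history: list[dict[str, float]] = []
    for _ in range(config.epochs):
        ia, ib = rng.permutation(len(a)), rng.permutation(len(b))
        nb = max(len(a), len(b)) // bs or 1
        cyc, adv_g, adv_d = [], [], []
        for k in range(nb):
            xa = Tensor(a[ia[(k * bs + np.arange(bs)) % len(a)]][:, None])
            xb = Tensor(b[ib[(k * bs + np.arange(bs)) % len(b)]][:, None])
            fake_b = g_n2h(xa)
            fake_a = g_h2n(xb)
            # discriminators on detached fakes
            opt_d.zero_grad()
            d_loss = (
                ((d_h(xb) - 1.0) ** 2).mean() + (d_h(Tensor(fake_b.data)) ** 2).mean()
                + ((d_n(xa) - 1.0) ** 2).mean() + (d_n(Tensor(fake_a.data)) ** 2).mean()
            ) * 0.5
            d_loss.backward()
            opt_d.step()
            # generators
            opt_g.zero_grad()
            fake_b = g_n2h(xa)
            fake_a = g_h2n(xb)
            cycle_a = _l1(g_h2n(fake_b), xa)
            cycle_b = _l1(g_n2h(fake_a), xb)
            g_adv = ((d_h(fake_b) - 1.0) ** 2).mean() + ((d_n(fake_a) - 1.0) ** 2).mean()
            g_loss = g_adv + config.cycle_weight * (cycle_a + cycle_b)
            g_loss.backward()
            opt_g.step()
            cyc.append(0.5 * (cycle_a.item() + cycle_b.item()))
            adv_g.append(g_adv.item())
            adv_d.append(d_loss.item())
        history.append(
            {"cycle": float(np.mean(cyc)), "adv_g": float(np.mean(adv_g)),
             "adv_d": float(np.mean(adv_d))}
        )
    return g_n2h, g_h2n, history


def cycle_reconstruction_error(g_fwd: ResidualGenerator, g_bwd: ResidualGenerator,
                               images: np.ndarray) -> float:
    """Mean L1 cycle error ||F(G(x)) - x|| over a stack of images."""
    x = np.asarray(images, dtype=float)
    return float(np.abs(g_bwd.translate(g_fwd.translate(x)) - x).mean())


# ---------------------------------------------------------------------------
# estimator front-ends
# ---------------------------------------------------------------------------


class _AugmenterBase(BaseEstimator):
    def fit(self, images_normal, images_high):  # pragma: no cover - interface
        raise NotImplementedError

    def _sources(self, domain: str) -> np.ndarray:
        return self.sources_normal_ if domain == "normal" else self.sources_high_

    def generate(self, n_per_class: int, seed: int = 0) -> AugmentedSet:
        """Exactly ``n_per_class`` generated images per domain."""
        if n_per_class < 0:
            raise ValueError("n_per_class must be >= 0")
        if not hasattr(self, "sources_normal_"):
            raise RuntimeError("augmenter is not fitted")
        rng = np.random.default_rng(seed)
        images, domains, source_ids = [], [], []
        for domain in ("normal", "high"):
            out = self._generate_domain(domain, n_per_class, rng)
            for im, sid in out:
                images.append(np.clip(im, 0.0, 1.0))
                domains.append(domain)
                source_ids.append(sid)
        return AugmentedSet(images, domains, source_ids)


class CycleGANAugmenter(_AugmenterBase):
    """Cycle-consistent augmenter: fit trains both generators."""

    def __init__(self, config: CycleConfig = CycleConfig()):
        self.config = config

    def fit(self, images_normal, images_high) -> "CycleGANAugmenter":
        if len(images_normal) == 0 or len(images_high) == 0:
            raise ValueError("both domains must be non-empty")
        self.sources_normal_ = np.stack([np.asarray(i, float) for i in images_normal])
        self.sources_high_ = np.stack([np.asarray(i, float) for i in images_high])
        self.g_n2h_, self.g_h2n_, self.history_ = train_cyclegan(
            self.sources_normal_, self.sources_high_, self.config
        )
        return self

    def _generate_domain(self, domain, n, rng):
        # translate sources from the opposite domain into this one
        src = self._sources("high" if domain == "normal" else "normal")
        gen = self.g_h2n_ if domain == "normal" else self.g_n2h_
        if len(src) == 0:
            raise ValueError("no source images")
        idx = rng.integers(0, len(src), size=n)
        out = []
        for b0 in range(0, n, 32):
            chunk = idx[b0 : b0 + 32]
            imgs = gen.translate(src[chunk])
            out.extend(zip(list(imgs), chunk.tolist()))
        return out


class ClassicAugmenter(_AugmenterBase):
    """Geometric/intensity jitter within each domain (no training).

    Horizontal flips, small cyclic translations, multiplicative intensity
    jitter and light additive noise. Fast enough for CI-scale pipelines.
    """

    def __init__(self, max_shift: int = 3, intensity_jitter: float = 0.1,
                 noise_sd: float = 0.01):
        self.max_shift = max_shift
        self.intensity_jitter = intensity_jitter
        self.noise_sd = noise_sd

    def fit(self, images_normal, images_high) -> "ClassicAugmenter":
        if len(images_normal) == 0 or len(images_high) == 0:
            raise ValueError("both domains must be non-empty")
        self.sources_normal_ = np.stack([np.asarray(i, float) for i in images_normal])
        self.sources_high_ = np.stack([np.asarray(i, float) for i in images_high])
        return self

    def _generate_domain(self, domain, n, rng):
        src = self._sources(domain)
        idx = rng.integers(0, len(src), size=n)
        out = []
        for sid in idx:
            im = src[sid].copy()
            if rng.random() < 0.5:
                im = im[:, ::-1]
            sh, sv = rng.integers(-self.max_shift, self.max_shift + 1, size=2)
            im = np.roll(im, (sv, sh), axis=(0, 1))
            gain = 1.0 + rng.uniform(-self.intensity_jitter, self.intensity_jitter)
            im = im * gain + rng.normal(0, self.noise_sd, im.shape)
            out.append((im, int(sid)))
        return out


def generate_augmented(augmenter: _AugmenterBase, n_per_class: int,
                       seed: int = 0) -> AugmentedSet:
    """Thin wrapper over ``augmenter.generate`` (fitted augmenter required)."""
    return augmenter.generate(n_per_class, seed)
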
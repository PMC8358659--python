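"""Seeded generators for the benchmark data this package is tested on.

Two generators:

* :func:`generate_domains` — two labeled feature domains whose *marginal*
  distributions differ (different orthogonal embeddings, a latent
  rotation, a translation and additive noise in the target) while the
  *class-conditional* latent structure is shared: both domains draw from
  the same latent class means, placed at scaled simplex vertices. This is
  the setting domain adaptation assumes — P(source) != P(target) but
  matched class-conditionals.
* :func:`generate_class_signals` — band-limited multichannel signals with
  class-dependent spectral content (a class-specific tone over a pink-ish
  background), used to exercise the feature extractors.

Both are fully deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .domain import LabeledDomain
from .errors import ConfigError, InputError
from .features import Epoch

__all__ = [
    "ShiftConfig",
    "DomainGroundTruth",
    "generate_domains",
    "generate_class_signals",
    "default_benchmark_config",
]


@dataclass
class ShiftConfig:
    """Parameters of the two-domain generator.

    ``class_separation`` is the pairwise distance between latent class
    means (unit within-class latent noise, so separation 4 means ~4
    sigma); ``rotation_angle`` rotates the target's latent coordinates in
    the plane of the first two latent axes; ``translation_norm`` shifts
    the target in observation space; ``noise_sd`` is the observation
    noise in both domains. ``share_embedding`` reuses the source
    embedding for the target (requires d_s == d_t), giving identical
    distributions when rotation and translation are also zero.
    """

    C: int = 3
    latent_dim: int = 5
    d_s: int = 20
    d_t: int = 20
    n_s: int = 150
    n_t_labeled_per_class: int = 3
    n_t_test: int = 300
    class_separation: float = 4.0
    rotation_angle: float = np.pi / 6
    translation_norm: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0
    share_embedding: bool = False

    def __post_init__(self) -> None:
        if self.C < 2:
            raise ConfigError("need at least two classes")
        if self.latent_dim < self.C - 1:
            raise ConfigError(
                f"latent_dim={self.latent_dim} cannot hold a {self.C}-class simplex "
                f"(needs >= C-1 = {self.C - 1})"
            )
        if min(self.d_s, self.d_t) < self.latent_dim:
            raise ConfigError("observation dims must be >= latent_dim")
        if self.n_t_labeled_per_class < 1:
            raise ConfigError("n_t_labeled_per_class must be >= 1")
        if self.class_separation <= 0:
            raise ConfigError("class_separation must be > 0")
        if self.share_embedding and self.d_s != self.d_t:
            raise ConfigError("share_embedding requires d_s == d_t")


def default_benchmark_config(seed: int = 0) -> ShiftConfig:
    """The default synthetic benchmark: 3 classes, 5 latent dims, 20-dim
    observations, 150 source samples, 3 labeled target samples per class,
    300 target test samples, separation 4, 30-degree latent rotation,
    translation 2, noise 0.5."""
    return ShiftConfig(seed=seed)


@dataclass
class DomainGroundTruth:
    """What the generator actually used (for parameter-recovery checks)."""

    class_means: np.ndarray        # latent_dim x C
    embedding_s: np.ndarray        # d_s x latent_dim, orthonormal columns
    embedding_t: np.ndarray        # d_t x latent_dim (includes the rotation)
    translation: np.ndarray        # d_t
    latents_s: np.ndarray
    latents_t_labeled: np.ndarray
    latents_t_test: np.ndarray


def _simplex_means(C: int, latent_dim: int, separation: float) -> np.ndarray:
    """C latent class means with all pairwise distances == separation.

    Scaled standard-simplex vertices ``(separation/sqrt(2)) * e_i`` when
    they fit (latent_dim >= C): class directions are then mutually
    orthogonal and off-origin, like the positive band-power/entropy
    features the generator stands in for. Falls back to a centered
    regular simplex in C-1 dimensions when latent_dim == C-1.
    """
    if latent_dim >= C:
        means = np.zeros((latent_dim, C))
        means[:C, :] = np.eye(C) * (separation / np.sqrt(2.0))
        return means
    V = np.eye(C)
    V = V - V.mean(axis=1, keepdims=True)
    V = V / np.sqrt(2.0) * separation  # centered; pairwise distance == separation
    U, s, _ = np.linalg.svd(V, full_matrices=False)
    means = np.zeros((latent_dim, C))
    means[: C - 1, :] = (U[:, : C - 1] * s[: C - 1]).T
    return means


def _orthonormal_embedding(d: int, latent_dim: int, rng: np.random.Generator) -> np.ndarray:
    Q, _ = np.linalg.qr(rng.standard_normal((d, latent_dim)))
    return Q


def _latent_rotation(latent_dim: int, angle: float) -> np.ndarray:
    R = np.eye(latent_dim)
    c, s = np.cos(angle), np.sin(angle)
    R[0, 0], R[0, 1], R[1, 0], R[1, 1] = c, -s, s, c
    return R


def generate_domains(
    cfg: ShiftConfig, return_truth: bool = False
) -> Tuple[LabeledDomain, LabeledDomain, LabeledDomain] | Tuple[
    LabeledDomain, LabeledDomain, LabeledDomain, DomainGroundTruth
]:
    """Draw (source, target-labeled, target-test) feature domains.

    Latents: ``z ~ N(mean_c, I)`` with class means at scaled simplex
    vertices. Source observations are ``A_s z + eps``; target observations
    are ``A_t R z + t + eps`` with a latent rotation ``R``, translation
    ``t`` and ``eps ~ N(0, noise_sd^2 I)``. Classes are balanced (the
    source's ``n_s`` and the test split's ``n_t_test`` are rounded down
    to multiples of ``C``).
    """
    rng = np.random.default_rng(cfg.seed)
    means = _simplex_means(cfg.C, cfg.latent_dim, cfg.class_separation)
    A_s = _orthonormal_embedding(cfg.d_s, cfg.latent_dim, rng)
    A_t = A_s if cfg.share_embedding else _orthonormal_embedding(cfg.d_t, cfg.latent_dim, rng)
    R = _latent_rotation(cfg.latent_dim, cfg.rotation_angle)
    if cfg.translation_norm > 0:
        t_dir = rng.standard_normal(cfg.d_t)
        t = cfg.translation_norm * t_dir / np.linalg.norm(t_dir)
    else:
        t = np.zeros(cfg.d_t)

    def draw(per_class: int, target: bool) -> Tuple[LabeledDomain, np.ndarray]:
        labels = np.repeat(np.arange(1, cfg.C + 1), per_class)
        Z = np.column_stack(
            [means[:, c] + rng.standard_normal(cfg.latent_dim) for c in labels - 1]
        )
        if target:
            X = A_t @ (R @ Z) + t[:, None]
            noise_dim = cfg.d_t
        else:
            X = A_s @ Z
            noise_dim = cfg.d_s
        X = X + cfg.noise_sd * rng.standard_normal((noise_dim, Z.shape[1]))
        return LabeledDomain(X, labels), Z

    Ys, Zs = draw(cfg.n_s // cfg.C, target=False)
    Yt_lab, Zl = draw(cfg.n_t_labeled_per_class, target=True)
    Yt_test, Zt = draw(cfg.n_t_test // cfg.C, target=True)
    if not return_truth:
        return Ys, Yt_lab, Yt_test
    truth = DomainGroundTruth(
        class_means=means,
        embedding_s=A_s,
        embedding_t=A_t @ R,
        translation=t,
        latents_s=Zs,
        latents_t_labeled=Zl,
        latents_t_test=Zt,
    )
    return Ys, Yt_lab, Yt_test, truth


def generate_class_signals(
    n_epochs: int,
    channels: int,
    sampling_rate: float,
    class_band_map: Dict[int, Tuple[float, float]],
    noise_sd: float = 0.5,
    seed: int = 0,
    duration: float = 4.0,
) -> List[Epoch]:
    """Multichannel epochs whose spectral content depends on the class.

    Each epoch is a unit-amplitude sinusoid at a frequency drawn from the
    middle half of its class's band (seeded random phase per channel)
    plus 1/f-shaped background noise of standard deviation ``noise_sd``.
    With ``noise_sd = 0`` each channel is a pure tone. Labels cycle
    through the classes in ``class_band_map``.
    """
    nyq = sampling_rate / 2.0
    for c, (low, high) in class_band_map.items():
        if not 0 < low < high:
            raise InputError(f"invalid band {low, high} for class {c}")
        if high >= nyq:
            raise InputError(f"class {c} band edge {high} Hz >= Nyquist {nyq} Hz")
    rng = np.random.default_rng(seed)
    n_times = int(round(duration * sampling_rate))
    tvec = np.arange(n_times) / sampling_rate
    classes = sorted(class_band_map)
    epochs: List[Epoch] = []
    for e in range(n_epochs):
        c = classes[e % len(classes)]
        low, high = class_band_map[c]
        span = high - low
        f0 = rng.uniform(low + 0.25 * span, high - 0.25 * span)
        sig = np.empty((channels, n_times))
        for ch in range(channels):
            phase = rng.uniform(0, 2 * np.pi)
            tone = np.sin(2 * np.pi * f0 * tvec + phase)
            if noise_sd > 0:
                white = rng.standard_normal(n_times)
                spec = np.fft.rfft(white)
                freqs = np.fft.rfftfreq(n_times, d=1.0 / sampling_rate)
                shaping = np.ones_like(freqs)
                shaping[1:] = 1.0 / np.sqrt(freqs[1:])
                shaping[0] = 0.0
                pink = np.fft.irfft(spec * shaping, n=n_times)
                pink *= noise_sd / pink.std()
                tone = tone + pink
            sig[ch] = tone
        epochs.append(Epoch(sig, sampling_rate, label=c))
    return epochs
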
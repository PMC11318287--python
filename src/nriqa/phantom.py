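"""Synthetic anatomy-like phantoms with controlled degradation.

Stands in for clinical MRI collections: piecewise-smooth ellipse phantoms
with an optional bandpass texture field, corrupted by Gaussian or Rician
noise at a known variance, so that every downstream stage of the quality
pipeline can be exercised against a known monotone ground truth.

Ground-truth quality is defined as ``true_score = 1 - v / v_max`` where
``v`` is the noise variance on the [0, 1] intensity scale and
``v_max = max(1.0, max(variances))``; an image is labelled ``High`` when
its score is at least 0.5.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, InvalidArgumentError

__all__ = [
    "Phantom",
    "SplitSpec",
    "generate_phantom",
    "add_noise",
    "make_dataset",
    "split_sizes",
    "save_dataset",
]

#: Partition names, in the order the split fractions are given.
PARTITIONS = ("train", "test", "validation")


@dataclass(frozen=True)
class Phantom:
    """One synthetic image with its known degradation level and quality."""

    image: np.ndarray
    noise_variance: float
    true_score: float
    label: str
    seed: int

    def __post_init__(self) -> None:
        if self.noise_variance < 0:
            raise InvalidArgumentError("noise_variance must be >= 0")
        if not 0.0 <= self.true_score <= 1.0:
            raise InvalidArgumentError("true_score must lie in [0, 1]")
        expected = "High" if self.true_score >= 0.5 else "Low"
        if self.label != expected:
            raise InvalidArgumentError(
                f"label {self.label!r} inconsistent with score {self.true_score}"
            )


@dataclass(frozen=True)
class SplitSpec:
    """Train/test/validation fractions plus the overall dataset size."""

    fractions: tuple[float, float, float] = (0.75, 0.15, 0.10)
    overall: int = 1

    def __post_init__(self) -> None:
        if len(self.fractions) != 3:
            raise InvalidArgumentError("fractions must be a triple")
        if any(not (0.0 < f < 1.0) for f in self.fractions):
            raise InvalidArgumentError("each fraction must lie in (0, 1)")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise InvalidArgumentError("fractions must sum to 1")
        if self.overall < 1:
            raise InvalidArgumentError("overall must be positive")


def generate_phantom(
    size: int, n_ellipses: int, texture_strength: float, seed: int
) -> np.ndarray:
    """Render a clean piecewise-smooth phantom image.

    The image contains ``n_ellipses`` overlapping constant-intensity
    ellipses over a dark background; a bandpass (difference-of-Gaussians)
    texture field scaled by ``texture_strength`` is added on top, and the
    result is clipped to [0, 1].  Deterministic given ``seed``.
    """
    if size < 16:
        raise InvalidArgumentError("size must be >= 16")
    if n_ellipses < 1:
        raise InvalidArgumentError("n_ellipses must be positive")
    if not 0.0 <= texture_strength <= 1.0:
        raise InvalidArgumentError("texture_strength must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    img = np.full((size, size), 0.1)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    for _ in range(n_ellipses):
        cy, cx = rng.uniform(0.25 * size, 0.75 * size, size=2)
        ay = rng.uniform(0.10 * size, 0.35 * size)
        ax = rng.uniform(0.10 * size, 0.35 * size)
        theta = rng.uniform(0.0, math.pi)
        intensity = rng.uniform(0.3, 0.9)
        dy, dx = yy - cy, xx - cx
        u = dy * math.cos(theta) + dx * math.sin(theta)
        v = -dy * math.sin(theta) + dx * math.cos(theta)
        inside = (u / ay) ** 2 + (v / ax) ** 2 <= 1.0
        img[inside] = intensity

    if texture_strength > 0.0:
        noise = rng.standard_normal((size, size))
        band = gaussian_filter(noise, 1.0) - gaussian_filter(noise, 3.0)
        peak = np.abs(band).max()
        if peak > 0:
            band /= peak
        img = img + 0.15 * texture_strength * band

    return np.clip(img, 0.0, 1.0)


def add_noise(
    image: np.ndarray, variance: float, model: str = "gaussian", seed: int = 0
) -> np.ndarray:
    """Corrupt an image with Gaussian or Rician noise of the given variance.

    Gaussian: ``clip(image + e)`` with ``e ~ N(0, variance)``.
    Rician (MRI magnitude model): ``clip(sqrt((image + e1)^2 + e2^2))`` with
    independent ``e1, e2 ~ N(0, variance)``; on zero signal this reduces to
    a Rayleigh field with mean ``sqrt(variance * pi / 2)``.
    """
    if variance < 0:
        raise InvalidArgumentError("variance must be >= 0")
    if model not in ("gaussian", "rician"):
        raise ConfigurationError(f"unknown noise model {model!r}")
    image = np.asarray(image, dtype=float)
    if variance == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(variance)
    if model == "gaussian":
        noisy = image + rng.normal(0.0, sigma, image.shape)
    else:
        e1 = rng.normal(0.0, sigma, image.shape)
        e2 = rng.normal(0.0, sigma, image.shape)
        noisy = np.sqrt((image + e1) ** 2 + e2**2)
    return np.clip(noisy, 0.0, 1.0)


def split_sizes(
    overall: int, fractions: Sequence[float]
) -> tuple[tuple[float, float, float], tuple[int, int, int]]:
    """Exact and integer partition sizes for a train/test/validation split.

    ``expected`` is the exact real-valued product ``overall * fraction`` per
    part (it may be fractional).  ``realized`` floors each expected size and
    assigns the remaining items to the training part, so the realized sizes
    always sum to ``overall``.
    """
    spec = SplitSpec(tuple(fractions), overall)  # validates
    expected = tuple(spec.overall * f for f in spec.fractions)
    floors = [math.floor(e + 1e-9) for e in expected]  # guard fp, e.g. 0.15*n
    remainder = spec.overall - sum(floors)
    floors[0] += remainder
    return expected, tuple(floors)


def make_dataset(
    n: int,
    variances: Sequence[float],
    split: SplitSpec | None = None,
    seed: int = 0,
    *,
    size: int = 64,
    n_ellipses: int = 4,
    texture_strength: float = 0.3,
    noise_model: str = "gaussian",
) -> tuple[list[Phantom], list[str]]:
    """Generate ``n`` phantoms cycling through a noise-variance grid.

    Returns the phantoms and a parallel list of partition names
    (``train``/``test``/``validation``).  Each phantom gets distinct clean
    content (derived seed), noise at the cycled variance, and
    ``true_score = 1 - v / v_max`` with ``v_max = max(1.0, max(variances))``.
    """
    if n < 1:
        raise InvalidArgumentError("n must be positive")
    if not variances or any(v < 0 for v in variances):
        raise InvalidArgumentError("variances must be non-empty and >= 0")
    if split is None:
        split = SplitSpec(overall=n)
    if split.overall != n:
        split = SplitSpec(split.fractions, n)

    _, realized = split_sizes(n, split.fractions)
    if any(r < 1 for r in realized):
        raise InvalidArgumentError(
            f"n={n} cannot supply at least one item per partition {realized}"
        )

    v_max = max(1.0, max(variances))
    rng = np.random.default_rng(seed)
    phantoms: list[Phantom] = []
    for i in range(n):
        v = float(variances[i % len(variances)])
        item_seed = int(rng.integers(0, 2**31 - 1))
        clean = generate_phantom(size, n_ellipses, texture_strength, item_seed)
        noisy = add_noise(clean, v, noise_model, item_seed + 1)
        score = 1.0 - v / v_max
        label = "High" if score >= 0.5 else "Low"
        phantoms.append(Phantom(noisy, v, score, label, item_seed))

    order = rng.permutation(n)
    partitions = [""] * n
    start = 0
    for part, count in zip(PARTITIONS, realized):
        for idx in order[start : start + count]:
            partitions[idx] = part
        start += count
    return phantoms, partitions


def save_dataset(
    phantoms: Sequence[Phantom],
    partitions: Sequence[str],
    out_dir: str | Path,
    fmt: str = "png",
) -> Path:
    """Write phantom images plus a CSV manifest; returns the manifest path.

    ``fmt`` is ``png`` (16-bit grayscale) or ``npy`` (lossless float).
    Manifest columns: image_path, noise_variance, true_score, label,
    partition.
    """
    from .io import write_image  # local import to avoid cycle

    if fmt not in ("png", "npy"):
        raise ConfigurationError(f"unsupported dataset format {fmt!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["image_path", "noise_variance", "true_score", "label", "partition"]
        )
        for i, (ph, part) in enumerate(zip(phantoms, partitions)):
            name = f"phantom_{i:05d}.{fmt}"
            write_image(ph.image, out / name)
            writer.writerow([name, ph.noise_variance, ph.true_score, ph.label, part])
    return manifest
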
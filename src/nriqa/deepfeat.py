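"""Deep structural feature stage.

Provides the leaky-ReLU activation, compound (depth/width/resolution)
architecture scaling under FLOPs and memory budgets, bilinear input
resizing, and a pluggable feature-extractor contract.  The default backend
is a compact stack of depthwise-separable convolution blocks with
fixed-seed random weights and a random projection head — a deterministic,
dependency-free structural-feature extractor.  It is not a trained
network; it supplies reproducible image descriptors sensitive to
structure and corruption, and any trained extractor can be plugged in
through the same interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import correlate
from skimage.transform import resize as _sk_resize

from .errors import (
    BackendError,
    ConstraintViolationError,
    InvalidArgumentError,
    InvalidInputError,
)

__all__ = [
    "BlockSpec",
    "ScalingConfig",
    "DeepFeatureBackend",
    "RandomProjectionConvBackend",
    "leaky_relu",
    "scale_architecture",
    "resize_input",
    "extract_deep_features",
    "fuse_features",
    "MinMaxNormalizer",
]


def leaky_relu(x, slope: float = 0.01):
    """Elementwise ``max(slope * x, x)``.

    Identity for non-negative inputs; a small linear leak (default 0.01)
    for negative inputs, so gradients never vanish entirely on the
    negative side.
    """
    if not 0.0 < slope < 1.0:
        raise InvalidArgumentError("slope must lie in (0, 1)")
    return np.maximum(np.multiply(slope, x), x)


@dataclass(frozen=True)
class BlockSpec:
    """One convolution stage: repeat count, spatial size, channel width."""

    repeats: int
    spatial: tuple[int, int]
    channels: int


@dataclass(frozen=True)
class ScalingConfig:
    """Compound-scaling coefficients, base architecture, and budgets.

    ``depth_coeff`` multiplies block repeat counts, ``width_coeff``
    multiplies channel widths, ``resolution_coeff`` multiplies the input
    resolution.  Estimated FLOPs and parameter counts of the scaled
    network must stay within ``flops_budget`` and ``memory_budget``.
    """

    depth_coeff: float = 1.0
    width_coeff: float = 1.0
    resolution_coeff: float = 1.0
    base_blocks: tuple[BlockSpec, ...] = (
        BlockSpec(1, (64, 64), 8),
        BlockSpec(1, (32, 32), 16),
        BlockSpec(2, (16, 16), 32),
    )
    base_resolution: int = 64
    flops_budget: float = 1e12
    memory_budget: float = 1e9

    def __post_init__(self) -> None:
        for name in ("depth_coeff", "width_coeff", "resolution_coeff"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        if self.flops_budget <= 0 or self.memory_budget <= 0:
            raise InvalidArgumentError("budgets must be positive")


def _block_costs(blocks: tuple[BlockSpec, ...], kernel: int = 3) -> tuple[float, float]:
    """Rough FLOPs and parameter-count estimates for a block list."""
    flops = 0.0
    params = 0.0
    for b in blocks:
        spatial = b.spatial[0] * b.spatial[1]
        per_layer = spatial * (b.channels * kernel**2 + b.channels**2)
        flops += b.repeats * per_layer
        params += b.repeats * (b.channels * kernel**2 + b.channels**2)
    return flops, params


def scale_architecture(cfg: ScalingConfig) -> tuple[tuple[BlockSpec, ...], int]:
    """Apply compound scaling and check the resource budgets.

    Repeats scale as ``ceil(a * T)``; channels as ``ceil(b * R)`` rounded
    up to even; spatial sizes and the input resolution scale by ``c``
    (rounded).  Raises :class:`ConstraintViolationError` naming the budget
    if the estimated FLOPs or parameter count exceed it.
    """
    a, b, c = cfg.depth_coeff, cfg.width_coeff, cfg.resolution_coeff
    scaled = []
    for blk in cfg.base_blocks:
        repeats = math.ceil(a * blk.repeats)
        channels = math.ceil(b * blk.channels)
        if channels % 2:
            channels += 1
        spatial = (
            max(1, round(c * blk.spatial[0])),
            max(1, round(c * blk.spatial[1])),
        )
        scaled.append(BlockSpec(repeats, spatial, channels))
    scaled = tuple(scaled)
    resolution = max(1, round(c * cfg.base_resolution))
    flops, params = _block_costs(scaled)
    if flops > cfg.flops_budget:
        raise ConstraintViolationError(
            f"FLOPs budget exceeded: {flops:.3g} > {cfg.flops_budget:.3g}"
        )
    if params > cfg.memory_budget:
        raise ConstraintViolationError(
            f"memory budget exceeded: {params:.3g} > {cfg.memory_budget:.3g}"
        )
    return scaled, resolution


def resize_input(image: np.ndarray, side: int = 224) -> np.ndarray:
    """Bilinear resize to ``side x side``, clipped to [0, 1]."""
    if side < 8:
        raise InvalidArgumentError("side must be >= 8")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise InvalidInputError("image must be a non-empty 2-D array")
    if image.shape == (side, side):
        return image.copy()
    out = _sk_resize(image, (side, side), order=1, mode="reflect", anti_aliasing=False)
    return np.clip(out, 0.0, 1.0)


class DeepFeatureBackend:
    """Contract for a deep-feature extractor.

    Implementations expose ``name``, ``output_dim`` and ``input_side``
    attributes and a ``forward(image) -> vector`` method that is a pure
    function of the image and the backend's frozen state.
    """

    name: str = "abstract"
    output_dim: int = 0
    input_side: int = 64

    def forward(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class RandomProjectionConvBackend(DeepFeatureBackend):
    """Default extractor: random-weight depthwise-separable conv stack.

    Each block applies a 3x3 depthwise convolution, a pointwise channel
    mix, a leaky-ReLU, and 2x2 average pooling; the final feature map is
    global-average-pooled and projected to ``output_dim`` by a fixed
    random matrix.  Weights use He-style initialization drawn once from
    ``seed``, so features are deterministic.
    """

    def __init__(
        self,
        output_dim: int = 64,
        seed: int = 0,
        scaling: ScalingConfig | None = None,
    ) -> None:
        if output_dim < 1:
            raise InvalidArgumentError("output_dim must be positive")
        self.name = "random-projection-conv"
        self.output_dim = output_dim
        self.seed = seed
        scaling = scaling or ScalingConfig()
        self.blocks, self.input_side = scale_architecture(scaling)
        rng = np.random.default_rng(seed)
        self._weights = []
        in_ch = 1
        for blk in self.blocks:
            for _ in range(blk.repeats):
                depthwise = rng.normal(0.0, math.sqrt(2.0 / 9.0), (in_ch, 3, 3))
                pointwise = rng.normal(
                    0.0, math.sqrt(2.0 / in_ch), (blk.channels, in_ch)
                )
                self._weights.append((depthwise, pointwise))
                in_ch = blk.channels
        self._proj = rng.normal(0.0, math.sqrt(2.0 / in_ch), (output_dim, in_ch))

    def forward(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=float)[None, :, :]  # channels-first
        for depthwise, pointwise in self._weights:
            dw = np.stack(
                [correlate(x[c], depthwise[c], mode="reflect") for c in range(x.shape[0])]
            )
            x = np.tensordot(pointwise, dw, axes=([1], [0]))
            x = leaky_relu(x)
            h2, w2 = x.shape[1] // 2 * 2, x.shape[2] // 2 * 2
            x = x[:, :h2, :w2].reshape(x.shape[0], h2 // 2, 2, w2 // 2, 2).mean((2, 4))
        pooled = x.mean(axis=(1, 2))
        return self._proj @ pooled


def extract_deep_features(
    image: np.ndarray, backend: DeepFeatureBackend | None = None
) -> pd.Series:
    """Resize to the backend's input side and run its forward pass.

    Returns a named vector ``deep_000 .. deep_{D-1}``; backend failures
    are re-raised as :class:`BackendError` naming the backend.
    """
    backend = backend or RandomProjectionConvBackend()
    resized = resize_input(image, backend.input_side)
    try:
        vec = np.asarray(backend.forward(resized), dtype=float)
    except Exception as exc:  # noqa: BLE001 - wrapped per contract
        raise BackendError(f"backend {backend.name!r} failed: {exc}") from exc
    if vec.shape != (backend.output_dim,):
        raise BackendError(
            f"backend {backend.name!r} returned shape {vec.shape}, "
            f"expected ({backend.output_dim},)"
        )
    names = [f"deep_{i:03d}" for i in range(backend.output_dim)]
    return pd.Series(vec, index=names)


def fuse_features(texture: pd.Series, deep: pd.Series) -> pd.Series:
    """Concatenate the texture block (first) with the deep block."""
    if texture.empty or deep.empty:
        raise InvalidInputError("feature blocks must be non-empty")
    overlap = set(texture.index) & set(deep.index)
    if overlap:
        raise InvalidInputError(f"feature name collision: {sorted(overlap)}")
    return pd.concat([texture, deep])


@dataclass
class MinMaxNormalizer:
    """Per-feature min-max scaling fitted on the training partition only.

    ``transform`` maps each column with the stored training min/max and
    clips to [0, 1]; constant training columns map to 0.  Statistics are
    never recomputed on new data.
    """

    mins: pd.Series = field(default_factory=pd.Series)
    maxs: pd.Series = field(default_factory=pd.Series)

    def fit(self, table: pd.DataFrame) -> "MinMaxNormalizer":
        self.mins = table.min(axis=0)
        self.maxs = table.max(axis=0)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.mins.empty:
            raise InvalidInputError("normalizer has not been fitted")
        if list(table.columns) != list(self.mins.index):
            raise InvalidInputError("feature columns do not match fitted statistics")
        span = (self.maxs - self.mins).replace(0.0, np.inf)  # constant cols -> 0
        scaled = (table - self.mins) / span
        return scaled.clip(0.0, 1.0)

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)
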
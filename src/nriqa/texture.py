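"""Gray-level run-length matrices and the seven run-length descriptors.

A run is a maximal set of consecutive collinear pixels sharing the same
quantized gray level.  The run-length matrix ``Q[j, k]`` counts runs of
gray level ``j`` (1-based) and length ``k`` along one of four scan
directions; the descriptors computed from it are

    SRE    short-run emphasis            sum Q/k^2 / N_r
    LGLRE  low-gray-level run emphasis   sum j^2 Q / k^2 / N_r
    LRE    long-run emphasis             sum k^2 Q / N_r
    RLN    run-length non-uniformity     sum_k (sum_j Q)^2 / N_r
    GLN    gray-level non-uniformity     sum_j (sum_k Q)^2 / N_r
    RP     run percentage                N_r / M
    HGRE   high-gray-level run emphasis  sum j^2 Q / N_r

with ``N_r`` the total number of runs and ``M`` the number of pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidInputError

__all__ = [
    "RunLengthMatrix",
    "GlrlmFeatures",
    "FEATURE_NAMES",
    "DIRECTIONS",
    "quantize",
    "run_length_matrix",
    "glrlm_features",
    "texture_feature_vector",
]

FEATURE_NAMES = ("sre", "lglre", "lre", "rln", "gln", "rp", "hgre")
DIRECTIONS = (0, 45, 90, 135)


@dataclass(frozen=True)
class RunLengthMatrix:
    """Run counts for one scan direction.

    ``Q[j-1, k-1]`` counts runs of gray level ``j`` and length ``k``;
    ``n_pixels`` is the number of pixels of the source region, so
    ``sum_jk k * Q[j, k] == n_pixels``.
    """

    Q: np.ndarray
    n_pixels: int
    direction: int
    n_levels: int

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise InvalidArgumentError(f"direction must be one of {DIRECTIONS}")
        if np.any(self.Q < 0):
            raise InvalidInputError("run counts must be non-negative")


@dataclass(frozen=True)
class GlrlmFeatures:
    sre: float
    lglre: float
    lre: float
    rln: float
    gln: float
    rp: float
    hgre: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            [getattr(self, n) for n in FEATURE_NAMES], index=list(FEATURE_NAMES)
        )


def quantize(image: np.ndarray, n_levels: int) -> np.ndarray:
    """Uniformly bin [0, 1] intensities into levels 1..n_levels.

    Bins are left-closed: a value x maps to ``floor(x * n_levels) + 1``,
    clamped to ``n_levels`` (so exactly 1.0 falls in the top level and a
    boundary value lands in the higher of its two adjacent bins).
    """
    if n_levels < 2:
        raise InvalidArgumentError("n_levels must be >= 2")
    image = np.asarray(image, dtype=float)
    levels = np.floor(image * n_levels).astype(np.int64) + 1
    return np.clip(levels, 1, n_levels)


def _scan_lines(levels: np.ndarray, direction: int):
    """Yield the 1-D scan lines of an integer image for one direction."""
    h, w = levels.shape
    if direction == 0:
        for row in levels:
            yield row
    elif direction == 90:
        for col in levels.T:
            yield col
    elif direction == 45:  # up-right anti-diagonals
        flipped = levels[::-1]
        for off in range(-(h - 1), w):
            yield np.diagonal(flipped, offset=off)
    else:  # 135, down-right diagonals
        for off in range(-(h - 1), w):
            yield np.diagonal(levels, offset=off)


def _line_runs(line: np.ndarray):
    """(level, length) of each maximal run in a scan line."""
    if line.size == 0:
        return
    changes = np.flatnonzero(np.diff(line)) + 1
    starts = np.concatenate(([0], changes))
    ends = np.concatenate((changes, [line.size]))
    for s, e in zip(starts, ends):
        yield int(line[s]), int(e - s)


def run_length_matrix(
    levels: np.ndarray, direction: int = 0, n_levels: int | None = None
) -> RunLengthMatrix:
    """Count maximal equal-level runs along one scan direction.

    ``levels`` is a quantized (1-based) integer image; level 0 marks
    pixels excluded from the region of interest — such pixels break runs
    and are not counted.
    """
    levels = np.asarray(levels)
    if levels.ndim != 2 or levels.size == 0:
        raise InvalidInputError("levels must be a non-empty 2-D integer image")
    if n_levels is None:
        n_levels = int(levels.max())
    max_len = max(levels.shape)
    Q = np.zeros((n_levels, max_len), dtype=np.int64)
    n_pixels = 0
    for line in _scan_lines(levels, direction):
        for level, length in _line_runs(np.asarray(line)):
            if level == 0:
                continue
            Q[level - 1, length - 1] += 1
            n_pixels += length
    return RunLengthMatrix(Q, n_pixels, direction, n_levels)


def glrlm_features(rlm: RunLengthMatrix) -> GlrlmFeatures:
    """The seven run-length descriptors of a run-length matrix."""
    Q = rlm.Q.astype(float)
    n_runs = Q.sum()
    if n_runs == 0:
        raise InvalidInputError("run-length matrix contains no runs")
    j = np.arange(1, Q.shape[0] + 1, dtype=float)[:, None]
    k = np.arange(1, Q.shape[1] + 1, dtype=float)[None, :]
    sre = float((Q / k**2).sum() / n_runs)
    lglre = float((j**2 * Q / k**2).sum() / n_runs)
    lre = float((k**2 * Q).sum() / n_runs)
    rln = float((Q.sum(axis=0) ** 2).sum() / n_runs)
    gln = float((Q.sum(axis=1) ** 2).sum() / n_runs)
    rp = float(n_runs / rlm.n_pixels)
    hgre = float((j**2 * Q).sum() / n_runs)
    return GlrlmFeatures(sre, lglre, lre, rln, gln, rp, hgre)


def texture_feature_vector(
    image: np.ndarray,
    n_levels: int = 16,
    directions: tuple[int, ...] = DIRECTIONS,
    roi_mask: np.ndarray | None = None,
) -> pd.Series:
    """Seven-entry named texture block, averaged over scan directions.

    Per-direction descriptor vectors are computed on the quantized image
    (optionally restricted to ``roi_mask``) and averaged arithmetically.
    """
    if not directions:
        raise InvalidArgumentError("directions must be non-empty")
    for d in directions:
        if d not in DIRECTIONS:
            raise InvalidArgumentError(f"unknown direction {d}")
    levels = quantize(image, n_levels)
    if roi_mask is not None:
        mask = np.asarray(roi_mask, dtype=bool)
        if mask.shape != levels.shape:
            raise InvalidInputError("roi_mask shape must match image")
        levels = np.where(mask, levels, 0)
    per_dir = [
        glrlm_features(run_length_matrix(levels, d, n_levels)).as_series()
        for d in directions
    ]
    return pd.concat(per_dir, axis=1).mean(axis=1)
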
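"""Hybrid bilateral / adaptive-Wiener pre-processing filter.

The bilateral stage smooths with a product of a spatial Gaussian kernel and
an intensity-range Gaussian kernel, preserving edges; the Wiener stage then
attenuates residual stationary noise adaptively: each pixel is shrunk toward
its local mean by the factor ``P / (P + sigma^2)`` where ``P`` is the local
signal variance, so smoothing is weak where local contrast is high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .errors import InvalidArgumentError, InvalidInputError

__all__ = [
    "BilateralConfig",
    "WienerConfig",
    "bilateral_filter",
    "estimate_local_stats",
    "wiener_filter",
    "hybrid_denoise",
]


@dataclass(frozen=True)
class BilateralConfig:
    """Bilateral kernel parameters.

    spatial_sigma: width (pixels) of the spatial Gaussian kernel.
    range_sigma: width (intensity units) of the range Gaussian kernel.
    radius: half-width of the square neighborhood.
    """

    spatial_sigma: float = 1.5
    range_sigma: float = 0.1
    radius: int = 3

    def __post_init__(self) -> None:
        if not (np.isfinite(self.spatial_sigma) and self.spatial_sigma > 0):
            raise InvalidArgumentError("spatial_sigma must be finite and > 0")
        if not (np.isfinite(self.range_sigma) and self.range_sigma > 0):
            raise InvalidArgumentError("range_sigma must be finite and > 0")
        if self.radius < 1:
            raise InvalidArgumentError("radius must be >= 1")


@dataclass(frozen=True)
class WienerConfig:
    """Adaptive Wiener parameters: local window side and optional noise power.

    When ``noise_variance_override`` is None the noise power sigma^2 is
    estimated as the mean of the local variances over the image.
    """

    window: int = 5
    noise_variance_override: float | None = None

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise InvalidArgumentError("window must be odd and >= 3")
        if self.noise_variance_override is not None and self.noise_variance_override < 0:
            raise InvalidArgumentError("noise_variance_override must be >= 0")


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise InvalidInputError("image must be a non-empty 2-D array")
    if not np.all(np.isfinite(image)):
        raise InvalidInputError("image contains non-finite pixels")
    return image


def bilateral_filter(image: np.ndarray, cfg: BilateralConfig | None = None) -> np.ndarray:
    """Edge-preserving smoothing by a normalized spatial-times-range kernel.

    Each output pixel is ``sum_r I_r a(||r - n||) b(|I_r - I_n|) / K(n)``
    over the square neighborhood of half-width ``cfg.radius``, where ``a``
    and ``b`` are Gaussians with ``spatial_sigma`` and ``range_sigma`` and
    ``K(n)`` is the sum of the weights.  Borders are handled by reflecting
    the image.  The output is a convex combination of neighborhood values,
    so its range is bounded by the input range.
    """
    cfg = cfg or BilateralConfig()
    image = _check_image(image)
    r = cfg.radius
    # edge-duplicating reflection, matching scipy.ndimage's "reflect" mode
    padded = np.pad(image, r, mode="symmetric")
    num = np.zeros_like(image)
    den = np.zeros_like(image)
    inv2ss = 1.0 / (2.0 * cfg.spatial_sigma**2)
    inv2rs = 1.0 / (2.0 * cfg.range_sigma**2)
    h, w = image.shape
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            shifted = padded[r + dy : r + dy + h, r + dx : r + dx + w]
            weight = np.exp(
                -(dy * dy + dx * dx) * inv2ss - (shifted - image) ** 2 * inv2rs
            )
            num += weight * shifted
            den += weight
    return num / den


def estimate_local_stats(
    image: np.ndarray, window: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean and mean-of-squares over a reflected square window.

    Local variance is ``power - mean**2`` clamped at zero (the clamp absorbs
    rounding error of order 1e-12).
    """
    image = _check_image(image)
    if window < 3 or window % 2 == 0:
        raise InvalidArgumentError("window must be odd and >= 3")
    if window > min(image.shape):
        raise InvalidArgumentError(
            f"window {window} exceeds smallest image side {min(image.shape)}"
        )
    mean = uniform_filter(image, window, mode="reflect")
    power = uniform_filter(image**2, window, mode="reflect")
    return mean, power


def local_variance(mean: np.ndarray, power: np.ndarray) -> np.ndarray:
    """Clamped local variance from the two local moments."""
    return np.clip(power - mean**2, 0.0, None)


def wiener_filter(image: np.ndarray, cfg: WienerConfig | None = None) -> np.ndarray:
    """Adaptive (local-statistics) Wiener filter.

    Output pixel = ``mean + (f - mean) * P / (P + sigma^2)`` where ``mean``
    and ``P`` are the local mean and variance over the ``window``-sized
    neighborhood, and ``sigma^2`` is the global noise power (mean of local
    variances, unless overridden).  With ``sigma^2 = 0`` the filter is the
    identity; on a constant image it returns the constant.
    """
    cfg = cfg or WienerConfig()
    image = _check_image(image)
    mean, power = estimate_local_stats(image, cfg.window)
    var = local_variance(mean, power)
    if cfg.noise_variance_override is not None:
        sigma2 = float(cfg.noise_variance_override)
    else:
        sigma2 = float(var.mean())
    if sigma2 == 0.0:
        return image.copy()
    gain = var / (var + sigma2)
    return mean + (image - mean) * gain


def hybrid_denoise(
    image: np.ndarray,
    bcfg: BilateralConfig | None = None,
    wcfg: WienerConfig | None = None,
) -> np.ndarray:
    """Bilateral stage followed by the adaptive Wiener stage.

    Edge-preserving smoothing runs first so that the Wiener stage's local
    statistics are computed on an already edge-stabilized image.
    """
    return wiener_filter(bilateral_filter(image, bcfg), wcfg)
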
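"""Image reading and writing: PNG, TIFF, NPY grayscale in [0, 1]."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import IOFormatError

__all__ = ["read_image", "write_image", "LUMA_WEIGHTS"]

#: ITU-R BT.601 luma weights used to collapse RGB input to grayscale.
LUMA_WEIGHTS = (0.2125, 0.7154, 0.0721)

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".npy"}


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image as a float array in [0, 1].

    8/16-bit integer images are divided by their type maximum; RGB(A)
    input is converted to luminance with the BT.601 weights; NPY arrays
    are taken as already being on the [0, 1] scale.
    """
    path = Path(path)
    if path.suffix.lower() not in _IMAGE_SUFFIXES:
        raise IOFormatError(f"unsupported image format: {path}")
    try:
        if path.suffix.lower() == ".npy":
            arr = np.load(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise IOFormatError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        rgb = arr[..., :3].astype(float)
        if np.issubdtype(arr.dtype, np.integer):
            rgb /= np.iinfo(arr.dtype).max
        gray = rgb @ np.asarray(LUMA_WEIGHTS)
        return np.clip(gray, 0.0, 1.0)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / info.max
    return np.clip(arr.astype(float), 0.0, 1.0)


def write_image(image: np.ndarray, path: str | Path) -> Path:
    """Write a [0, 1] grayscale image; 16-bit for PNG/TIFF, lossless for NPY."""
    path = Path(path)
    image = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        np.save(path, image)
    elif suffix in (".png", ".tif", ".tiff"):
        iio.imwrite(path, (image * 65535.0 + 0.5).astype(np.uint16))
    else:
        raise IOFormatError(f"unsupported image format: {path}")
    return path
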
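"""Loading, calibration and preprocessing of seed-population images.

Seed scenes are photographed on white paper, so the background is the
brightest structure in the frame.  All downstream colour descriptors are
computed on *background-normalized* pixels: each channel is rescaled by a
single global factor so that the white paper maps to ~255, which removes
global lighting differences between acquisitions (under-/over-exposure)
without touching relative seed colour.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage as ndi

__all__ = [
    "CalibratedImage",
    "PreprocessedImage",
    "ImageDecodeError",
    "ImageFormatError",
    "load_image",
    "normalize_background",
    "preprocess",
    "luminance",
]

#: extensions accepted by :func:`load_image`
SUPPORTED_EXTENSIONS = {".jpg", ".jpeg", ".tif", ".tiff", ".png"}

#: BT.601 luminance weights used for the grayscale conversion
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class ImageDecodeError(RuntimeError):
    """Raised when a file exists but cannot be decoded as an image."""


class ImageFormatError(ValueError):
    """Raised for file extensions outside the supported set."""


@dataclass(frozen=True)
class CalibratedImage:
    """An 8-bit RGB raster plus optional physical pixel calibration.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array.
    um_per_px
        Physical size of one pixel in micrometres, if known.  Never
        inferred from burned-in scale bars; supplied by the user.
    source_id
        Image basename without extension; used to pair images with
        label files and to key output rows.
    """

    pixels: np.ndarray
    um_per_px: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {px.dtype}")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError("image must be at least 64x64 pixels")
        if self.um_per_px is not None and not self.um_per_px > 0:
            raise ValueError("um_per_px must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class PreprocessedImage:
    """Normalized + grayscale + blurred views of a calibrated image."""

    source: CalibratedImage
    normalized_rgb: np.ndarray
    background_level: tuple[float, float, float]
    grey: np.ndarray
    blurred: np.ndarray
    sigma: float
    normalization_skipped: bool = False

    @property
    def height(self) -> int:
        return int(self.grey.shape[0])

    @property
    def width(self) -> int:
        return int(self.grey.shape[1])


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    """Rescale an integer/float raster to 8 bit (full dtype range)."""
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return (arr.astype(np.float64) * (255.0 / 65535.0)).round().astype(np.uint8)
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(arr * 255.0, 0, 255).round().astype(np.uint8)
    info = np.iinfo(arr.dtype)
    scaled = (arr.astype(np.float64) - info.min) * (255.0 / (info.max - info.min))
    return scaled.round().astype(np.uint8)


def load_image(path: str | os.PathLike, um_per_px: float | None = None) -> CalibratedImage:
    """Load a JPEG/TIFF (or PNG) seed image as an 8-bit RGB raster.

    Grayscale sources are promoted to three identical channels; 16-bit
    TIFFs are linearly rescaled to 8 bit (65535 -> 255).
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise ImageFormatError(f"unsupported image extension {ext!r}: {path}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:  # Pillow raises several unrelated types
        raise ImageDecodeError(f"cannot decode image file {path}: {exc}") from exc
    arr = _to_uint8(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageDecodeError(f"unexpected raster shape {arr.shape} in {path}")
    source_id = os.path.splitext(os.path.basename(path))[0]
    return CalibratedImage(pixels=arr, um_per_px=um_per_px, source_id=source_id)


def luminance(rgb: np.ndarray) -> np.ndarray:
    """Weighted-sum grayscale conversion, rounded to uint8."""
    w = np.asarray(LUMA_WEIGHTS)
    grey = np.tensordot(rgb.astype(np.float64), w, axes=([-1], [0]))
    return np.clip(np.round(grey), 0, 255).astype(np.uint8)


def _otsu_brightness_threshold(values: np.ndarray) -> tuple[int, bool]:
    # local import avoids an import cycle (segmentation imports imaging types)
    from .segmentation import otsu_threshold

    hist = np.bincount(values.ravel(), minlength=256)[:256]
    return otsu_threshold(hist)


def normalize_background(
    img: CalibratedImage, sigma: float = 2.0
) -> tuple[np.ndarray, tuple[float, float, float], bool]:
    """Estimate the white-paper level and rescale each channel to it.

    The background region is the bright class of an Otsu split of the
    blurred luminance histogram.  Each channel is multiplied by the
    single global factor ``255 / median(channel | background)`` and
    clipped, so an under- or over-exposed acquisition maps back to a
    near-white paper level.

    Returns ``(normalized_rgb, background_level, skipped)`` where
    *skipped* is True for a degenerate (constant) image, passed through
    unchanged.
    """
    grey = luminance(img.pixels)
    blurred = _gaussian_u8(grey, sigma)
    thr, degenerate = _otsu_brightness_threshold(blurred)
    if degenerate:
        return img.pixels.copy(), (255.0, 255.0, 255.0), True
    bg = blurred > thr
    if not bg.any():  # pragma: no cover - bright class always non-empty
        return img.pixels.copy(), (255.0, 255.0, 255.0), True
    level = np.median(img.pixels[bg].reshape(-1, 3), axis=0)
    level = np.maximum(level, 1.0)  # division-safe
    scale = 255.0 / level
    out = np.clip(img.pixels.astype(np.float64) * scale, 0, 255).round().astype(np.uint8)
    return out, (float(level[0]), float(level[1]), float(level[2])), False


def _gaussian_u8(grey: np.ndarray, sigma: float) -> np.ndarray:
    blurred = ndi.gaussian_filter(grey.astype(np.float64), sigma=sigma, mode="reflect")
    return np.clip(np.round(blurred), 0, 255).astype(np.uint8)


def preprocess(img: CalibratedImage, sigma: float = 2.0) -> PreprocessedImage:
    """Background-normalize, convert to grayscale and Gaussian-smooth.

    ``sigma`` is the Gaussian standard deviation in pixels (default 2.0;
    scale it with zoom so that it stays well below the seed radius).
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    normalized, level, skipped = normalize_background(img, sigma=sigma)
    grey = luminance(normalized)
    blurred = _gaussian_u8(grey, sigma)
    return PreprocessedImage(
        source=img,
        normalized_rgb=normalized,
        background_level=level,
        grey=grey,
        blurred=blurred,
        sigma=sigma,
        normalization_skipped=skipped,
    )
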
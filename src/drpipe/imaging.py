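"""Fundus image preprocessing: border trimming, circular masking, resizing.

A fundus photograph is a bright, roughly circular retina on a near-black
frame. Preprocessing (1) crops away border rows/columns that are entirely
dark, (2) zeroes everything outside the inscribed circle whose diameter is
the smaller image side, (3) crops dark borders again (the circle step can
darken rows at the long edges), and (4) resizes to a square network input.

Images are ``uint8`` RGB arrays of shape (H, W, 3) throughout ("pixel
grids"). Grayscale files are promoted to 3 channels on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import AllDarkImage

__all__ = [
    "PreprocessConfig",
    "as_pixel_grid",
    "trim_dark_borders",
    "inscribe_circle_mask",
    "resize_image",
    "preprocess",
    "load_image",
    "save_image",
]

#: Intensity below which a pixel counts as background (strictly below).
DEFAULT_DARK_THRESHOLD = 7

#: Side length of the square network input, in pixels.
DEFAULT_TARGET_SIDE = 299


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    Attributes
    ----------
    dark_threshold:
        A row/column is removed while every channel of every one of its
        pixels is strictly below this value. Default 7.
    target_side:
        Output side length in pixels; both dimensions are forced to it
        (aspect ratio is not preserved). Default 299.
    """

    dark_threshold: int = DEFAULT_DARK_THRESHOLD
    target_side: int = DEFAULT_TARGET_SIDE

    def __post_init__(self) -> None:
        if not 0 <= self.dark_threshold <= 255:
            raise ValueError(f"dark_threshold must be in [0, 255], got {self.dark_threshold}")
        if self.target_side < 1:
            raise ValueError(f"target_side must be >= 1, got {self.target_side}")


def as_pixel_grid(image: np.ndarray) -> np.ndarray:
    """Coerce *image* to a valid (H, W, 3) uint8 pixel grid.

    2-D grayscale input is replicated across three channels. Raises
    ``ValueError`` for empty or otherwise malformed arrays.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"image must have positive dimensions, got {arr.shape}")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def trim_dark_borders(image: np.ndarray, threshold: int = DEFAULT_DARK_THRESHOLD) -> np.ndarray:
    """Crop contiguous border rows/columns whose pixels are all dark.

    A row (column) is dark when every channel of every pixel in it is
    strictly below *threshold*. Only the bounding box of the bright pixels
    survives; interior rows are never deleted, so anatomy is not sheared.

    Raises
    ------
    AllDarkImage
        If no pixel reaches the threshold in any channel.
    """
    image = as_pixel_grid(image)
    bright = image.max(axis=2) >= threshold
    rows = np.flatnonzero(bright.any(axis=1))
    cols = np.flatnonzero(bright.any(axis=0))
    if rows.size == 0 or cols.size == 0:
        raise AllDarkImage(
            f"every pixel has all channels < {threshold}; nothing would remain"
        )
    return image[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def inscribe_circle_mask(image: np.ndarray) -> np.ndarray:
    """Zero all pixels outside the largest inscribed circle.

    The circle is centred at the pixel-grid centre ((H-1)/2, (W-1)/2) with
    radius min(H, W)/2; a pixel survives when its centre lies within the
    radius. Idempotent, and never increases any pixel value.
    """
    image = as_pixel_grid(image)
    h, w = image.shape[:2]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = min(h, w) / 2.0
    yy, xx = np.ogrid[:h, :w]
    outside = (yy - cy) ** 2 + (xx - cx) ** 2 > radius * radius
    out = image.copy()
    out[outside] = 0
    return out


def resize_image(image: np.ndarray, side: int) -> np.ndarray:
    """Resize to ``side x side`` pixels with bilinear interpolation.

    Both dimensions are forced to *side*; the aspect ratio is deliberately
    not preserved (the preceding crop/mask steps have already made the
    retina roughly square).
    """
    image = as_pixel_grid(image)
    if side < 1:
        raise ValueError(f"side must be >= 1, got {side}")
    if image.shape[0] == side and image.shape[1] == side:
        return image.copy()
    pil = Image.fromarray(image)
    return np.asarray(pil.resize((side, side), Image.BILINEAR))


def preprocess(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Full preprocessing chain: trim -> circle mask -> trim -> resize.

    Raises
    ------
    AllDarkImage
        Propagated from the trimming steps.
    """
    config = config or PreprocessConfig()
    out = trim_dark_borders(image, config.dark_threshold)
    out = inscribe_circle_mask(out)
    out = trim_dark_borders(out, config.dark_threshold)
    return resize_image(out, config.target_side)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG file as an RGB pixel grid."""
    with Image.open(path) as img:
        return as_pixel_grid(np.asarray(img.convert("RGB")))


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write a pixel grid as PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(as_pixel_grid(image)).save(path)
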
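"""Image containers and PNG/TIFF I/O.

Intensities are kept as real values on the 0–255 scale regardless of the
source bit depth (smartphone sensors deliver 8-bit; 16-bit TIFF input is
normalized on load). Outputs are written as 8-bit by rounding half-up and
clipping, so filtered and unfiltered images stay on a common scale and
quality metrics computed on them are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RgbImage", "GrayImage", "load_image", "save_image"]


@dataclass
class RgbImage:
    """An H×W×3 raster of nonnegative intensities on the 0–255 scale.

    Channels are ordered R, G, B. ``bit_depth`` records the source depth
    (8 or 16); pixel values are always stored normalized to 0–255 reals.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"RGB image must be H×W×3, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if np.any(self.pixels < 0) or np.any(self.pixels > 255):
            raise ValueError("intensities must lie in [0, 255] after normalization")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def red(self) -> np.ndarray:
        return self.pixels[:, :, 0]

    @property
    def green(self) -> np.ndarray:
        return self.pixels[:, :, 1]

    @property
    def blue(self) -> np.ndarray:
        return self.pixels[:, :, 2]


@dataclass
class GrayImage:
    """A single-plane H×W raster of nonnegative 0–255 intensities."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"gray image must be H×W, got shape {self.pixels.shape}")
        if np.any(self.pixels < 0) or np.any(self.pixels > 255):
            raise ValueError("intensities must lie in [0, 255]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _to_uint8(pixels: np.ndarray) -> np.ndarray:
    # round half-up, not banker's rounding, so 0.5 -> 1 deterministically
    return np.clip(np.floor(pixels + 0.5), 0, 255).astype(np.uint8)


def load_image(path: str | Path) -> RgbImage:
    """Read a PNG or TIFF file into an :class:`RgbImage`.

    8-bit files load as-is; 16-bit files are scaled by 255/65535. Grayscale
    files are replicated into three channels; an alpha channel is dropped.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        raw = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        raw = iio.imread(path)
    raw = np.asarray(raw)
    if raw.dtype == np.uint16:
        pixels = raw.astype(np.float64) * (255.0 / 65535.0)
        depth = 16
    else:
        pixels = raw.astype(np.float64)
        depth = 8
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    elif pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    elif pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"unsupported image layout {raw.shape} in {path}")
    return RgbImage(np.clip(pixels, 0.0, 255.0), bit_depth=depth)


def save_image(image: RgbImage | GrayImage, path: str | Path) -> None:
    """Write an image as 8-bit PNG or TIFF (by file extension)."""
    path = Path(path)
    data = _to_uint8(image.pixels)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)
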
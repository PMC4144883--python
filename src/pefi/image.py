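"""Grayscale image container and file loading.

All algorithms in this package operate on 2-D single-channel images whose
gray levels live in [0, 1].  Integer images read from disk are rescaled by
the maximum representable value of their dtype (255 for 8-bit, 65535 for
16-bit); float images must already be in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio


class ImageFormatError(ValueError):
    """Raised for images that are not single-channel 2-D gray data."""


@dataclass(frozen=True)
class IntensityImage:
    """A 2-D gray-level image with values in [0, 1].

    Pixel (row, col) coordinates are 0-based; flattened pixel order is
    row-major throughout the package.
    """

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2 or arr.size == 0:
            raise ImageFormatError(
                f"expected a non-empty 2-D array, got shape {arr.shape}"
            )
        if not np.isfinite(arr).all():
            raise ImageFormatError("image contains non-finite values")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ImageFormatError(
                "gray levels must lie in [0, 1]; "
                f"found range [{arr.min():.4g}, {arr.max():.4g}]"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.values.size

    def window(self, origin: tuple[int, int], shape: tuple[int, int]) -> "IntensityImage":
        """Crop the window with the given top-left origin; must fit inside."""
        r0, c0 = origin
        wr, wc = shape
        if r0 < 0 or c0 < 0 or r0 + wr > self.n_rows or c0 + wc > self.n_cols:
            raise ValueError(f"window {shape} at {origin} exceeds image {self.shape}")
        return IntensityImage(self.values[r0 : r0 + wr, c0 : c0 + wc])


def as_intensity_image(values: np.ndarray) -> IntensityImage:
    """Wrap an array already scaled to [0, 1]."""
    return IntensityImage(np.asarray(values, dtype=np.float64))


def load_image(path: str | Path) -> IntensityImage:
    """Read a grayscale PNG/TIFF/PGM file and rescale gray levels to [0, 1].

    Unsigned-integer data are divided by the dtype maximum; float data must
    already be in [0, 1].  Multi-channel images are rejected.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ImageFormatError(
            f"{path}: expected single-channel 2-D image, got shape {arr.shape}"
        )
    if arr.dtype == bool:
        scaled = arr.astype(np.float64)
    elif np.issubdtype(arr.dtype, np.unsignedinteger) or np.issubdtype(
        arr.dtype, np.signedinteger
    ):
        if np.issubdtype(arr.dtype, np.signedinteger) and arr.min() < 0:
            raise ImageFormatError(f"{path}: negative integer gray levels")
        maxval = float(np.iinfo(arr.dtype).max)
        scaled = arr.astype(np.float64) / maxval
    elif np.issubdtype(arr.dtype, np.floating):
        scaled = arr.astype(np.float64)
        if scaled.size and (scaled.min() < 0.0 or scaled.max() > 1.0):
            raise ImageFormatError(f"{path}: float image not scaled to [0, 1]")
    else:
        raise ImageFormatError(f"{path}: unsupported dtype {arr.dtype}")
    return IntensityImage(scaled)


def save_image_u16(image: IntensityImage, path: str | Path) -> None:
    """Write an image as 16-bit PNG/TIFF (gray levels mapped to 0..65535)."""
    arr = np.round(image.values * 65535.0).astype(np.uint16)
    iio.imwrite(Path(path), arr)
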
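"""Raster I/O and conversion of dermoscopy images into candidate node masks.

Every clustering stage operates on a *node mask*: a 2-D boolean raster in
which ``True`` marks a pixel belonging to the point set handed to the
density scanner.  Lesions are darker than the surrounding skin, so a pixel
becomes a node when its intensity in the selected channel is at or below a
threshold; the blue channel is the conventional choice for dermoscopy.

Coordinate conventions, used everywhere in the package:

* ``x`` is the column, ``y`` the row, origin at the top-left, 0-based.
* Each pixel has a unique id ``pid = y * width + x`` (row-major).  The pid
  order is the total order used both for the deterministic visit order of
  the serial scanner and for canonical ("smallest pixel id") cluster ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import imageio.v3 as iio
import numpy as np

__all__ = [
    "CHANNELS",
    "Params",
    "PixelRef",
    "extract_nodes",
    "pixel_id",
    "pixel_from_id",
    "read_image",
    "read_mask",
    "write_image",
    "write_mask",
]

CHANNELS = {"R": 0, "G": 1, "B": 2}


class PixelRef(NamedTuple):
    """A pixel address: column ``x``, row ``y`` and row-major id ``pid``."""

    x: int
    y: int
    pid: int

    @classmethod
    def from_xy(cls, x: int, y: int, width: int) -> "PixelRef":
        return cls(x, y, y * width + x)


def pixel_id(x: int, y: int, width: int) -> int:
    """Row-major pixel id; strictly increasing in raster scan order."""
    return y * width + x


def pixel_from_id(pid: int, width: int) -> PixelRef:
    y, x = divmod(int(pid), width)
    return PixelRef(x, y, int(pid))


@dataclass(frozen=True)
class Params:
    """Density parameters: Manhattan radius ``eps`` and density floor ``min_pts``.

    ``min_pts`` counts the centre pixel itself (the ε-neighbourhood of a node
    always contains the node, at distance zero).
    """

    eps: int = 3
    min_pts: int = 4

    def __post_init__(self) -> None:
        if int(self.eps) != self.eps or self.eps < 1:
            raise ValueError(f"eps must be an integer >= 1, got {self.eps!r}")
        if int(self.min_pts) != self.min_pts or self.min_pts < 1:
            raise ValueError(f"min_pts must be an integer >= 1, got {self.min_pts!r}")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG or PPM image as an 8-bit RGB array of shape (H, W, 3).

    Grayscale images are promoted to three identical channels; an alpha
    channel, if present, is dropped.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise IOError(f"cannot read image {path}: expected 8-bit data, got {arr.dtype}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise IOError(f"cannot read image {path}: unsupported shape {arr.shape}")
    return np.ascontiguousarray(arr)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an 8-bit RGB (or grayscale) array as PNG/PPM based on suffix."""
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def extract_nodes(image: np.ndarray, channel: str = "B", threshold: int = 128) -> np.ndarray:
    """Threshold one channel of an RGB image into a boolean node mask.

    A pixel is a node when its channel value is <= ``threshold``: lesions are
    darker than skin, so low intensity marks lesion candidates.  Raising the
    threshold never removes a node.
    """
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {sorted(CHANNELS)}, got {channel!r}")
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold!r}")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    return image[:, :, CHANNELS[channel]] <= threshold


def read_mask(path: str | Path, expect_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a node mask from a PNG (nonzero = node) as a boolean array."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim == 3:  # tolerate RGB(A) masks; any nonzero channel counts
        arr = arr[:, :, :3].max(axis=2)
    mask = arr != 0
    if expect_shape is not None and mask.shape != tuple(expect_shape):
        raise ValueError(
            f"mask {path} has shape {mask.shape}, expected {tuple(expect_shape)}"
        )
    return mask


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean node mask as a single-channel PNG (255 = node)."""
    mask = np.asarray(mask, dtype=bool)
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))
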
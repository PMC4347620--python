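"""Small raster I/O helpers (8-bit PNG/TIFF via imageio)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image", "read_mask", "write_mask"]


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit image; RGBA is reduced to RGB."""
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[..., :3]
    return np.asarray(img, dtype=np.uint8)


def write_image(path: str | Path, img: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 single-channel mask PNG as a boolean raster."""
    m = iio.imread(path)
    if m.ndim == 3:
        m = m[..., 0]
    return np.asarray(m) > 127


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
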
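"""Linear-light RGB image container and PNG I/O.

All computation in the package happens on linear-light RGB reflectance /
intensity values in [0, 1] stored as float64 arrays of shape (H, W, 3).
Gamma-encoded files are linearized on load and re-encoded on save only if a
nonzero encoding exponent is requested; the default round trip is linear
16-bit TIFF, which preserves enough precision for calibration work.  8-bit
PNG is supported for both reading and writing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["LinearImage", "save_image", "load_image", "save_mask", "load_mask"]


@dataclass
class LinearImage:
    """An H×W×3 linear RGB image with an optional binary inclusion mask."""

    rgb: np.ndarray
    roi_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=float)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) array, got {self.rgb.shape}")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
            if self.roi_mask.shape != self.rgb.shape[:2]:
                raise ValueError("roi_mask shape does not match image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


def save_image(path: str | Path, image: LinearImage | np.ndarray, *, gamma: float = 1.0) -> None:
    """Write a linear image, scaled to the full integer range.

    ``.tif``/``.tiff`` files are written as 16-bit (values scaled to
    [0, 65535]); ``.png`` as 8-bit.
    """
    path = Path(path)
    rgb = image.rgb if isinstance(image, LinearImage) else np.asarray(image, dtype=float)
    encoded = np.clip(rgb, 0.0, 1.0)
    if gamma != 1.0:
        encoded = encoded ** (1.0 / gamma)
    if path.suffix.lower() in (".tif", ".tiff"):
        iio.imwrite(path, np.round(encoded * 65535.0).astype(np.uint16))
    else:
        iio.imwrite(path, np.round(encoded * 255.0).astype(np.uint8))


def load_image(path: str | Path, *, gamma: float = 1.0) -> LinearImage:
    """Read an 8- or 16-bit PNG/TIFF into linear [0, 1] floats.

    ``gamma`` is the encoding exponent used when the file was written; the
    loader inverts it (linear = stored**gamma).
    """
    raw = iio.imread(Path(path))
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    if raw.shape[2] > 3:
        raw = raw[:, :, :3]
    scale = 65535.0 if raw.dtype == np.uint16 else 255.0
    rgb = raw.astype(float) / scale
    if gamma != 1.0:
        rgb = rgb**gamma
    return LinearImage(rgb=rgb)


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary ROI mask as 8-bit PNG (nonzero = include)."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def load_mask(path: str | Path) -> np.ndarray:
    raw = iio.imread(Path(path))
    if raw.ndim == 3:
        raw = raw[:, :, 0]
    return raw > 0
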
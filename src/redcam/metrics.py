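"""Objective conjunctival redness metrics on ROI-masked linear RGB images.

Four metrics are computed over the region of interest (conjunctiva only —
iris, eyelids and saturated zones excluded):

* relative redness — the SUM over ROI pixels of R/(R+G+B).  It is a sum,
  not a mean, so it is directly proportional to the area considered.
* red–green difference — the mean over ROI of (R − G).
* red–blue difference — the mean over ROI of (R − B).
* red hue — the fraction of ROI pixels whose HSL hue is defined (chroma
  above a floor) and falls inside a red hue band, by default
  [330°, 360°) ∪ [0°, 30°).

N, the number of included non-saturated pixels, normalizes the last three.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ScoringError
from .image import LinearImage, load_image, load_mask

__all__ = [
    "ROISelection",
    "RednessScores",
    "build_roi",
    "hue_degrees",
    "score",
    "score_batch",
    "METRIC_NAMES",
]

METRIC_NAMES = ("relative_redness", "rg_diff", "rb_diff", "red_hue")

DEFAULT_SATURATION_THRESHOLD = 0.99
DEFAULT_RED_BAND = (330.0, 30.0)
DEFAULT_CHROMA_FLOOR = 0.01


@dataclass
class ROISelection:
    """The pixel set retained for scoring."""

    include_mask: np.ndarray
    n_pixels: int
    saturation_threshold: float


@dataclass
class RednessScores:
    relative_redness: float
    rg_diff: float
    rb_diff: float
    red_hue: float
    n_pixels: int

    def as_dict(self) -> dict[str, float]:
        return {
            "relative_redness": self.relative_redness,
            "rg_diff": self.rg_diff,
            "rb_diff": self.rb_diff,
            "red_hue": self.red_hue,
            "n_pixels": self.n_pixels,
        }


def build_roi(
    image: LinearImage | np.ndarray,
    mask: np.ndarray | None = None,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
) -> ROISelection:
    """Intersect the inclusion mask with the non-saturated pixel set.

    A pixel is saturated when any channel reaches the threshold (default
    0.99 in linear units, ≈253/255 in 8-bit).
    """
    rgb = image.rgb if isinstance(image, LinearImage) else np.asarray(image)
    if mask is None and isinstance(image, LinearImage):
        mask = image.roi_mask
    if mask is None:
        mask = np.ones(rgb.shape[:2], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != rgb.shape[:2]:
        raise ScoringError("mask shape does not match image")
    unsaturated = (rgb < saturation_threshold).all(axis=2)
    include = mask & unsaturated
    n = int(include.sum())
    if n == 0:
        cause = "inclusion mask is empty" if not mask.any() else "all masked pixels are saturated"
        raise ScoringError(f"no pixels left to score: {cause}")
    return ROISelection(include_mask=include, n_pixels=n, saturation_threshold=saturation_threshold)


def hue_degrees(rgb: np.ndarray, chroma_floor: float = DEFAULT_CHROMA_FLOOR) -> np.ndarray:
    """HSL hue in [0, 360) for an (..., 3) array; NaN where chroma < floor.

    Standard hexagonal hue: with C = max − min, H = 60·(((G−B)/C) mod 6)
    when R is the maximum, and analogously for G and B maxima.
    """
    rgb = np.asarray(rgb, dtype=float)
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    c = mx - mn
    safe_c = np.where(c > 0, c, 1.0)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    h = np.where(
        mx == r,
        np.mod((g - b) / safe_c, 6.0),
        np.where(mx == g, (b - r) / safe_c + 2.0, (r - g) / safe_c + 4.0),
    )
    h = 60.0 * h
    return np.where(c < chroma_floor, np.nan, h)


def _in_band(hue: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Membership in a hue band [lo, hi), wrapping through 0° when lo > hi."""
    lo, hi = band
    if lo <= hi:
        return (hue >= lo) & (hue < hi)
    return (hue >= lo) | (hue < hi)


def score(
    image: LinearImage | np.ndarray,
    roi: ROISelection,
    red_band: tuple[float, float] = DEFAULT_RED_BAND,
    chroma_floor: float = DEFAULT_CHROMA_FLOOR,
) -> RednessScores:
    """Compute the four redness metrics over a prepared ROI."""
    rgb = image.rgb if isinstance(image, LinearImage) else np.asarray(image)
    if roi.n_pixels < 1:
        raise ScoringError("ROI is empty")
    pixels = rgb[roi.include_mask]
    n = roi.n_pixels
    r, g, b = pixels[:, 0], pixels[:, 1], pixels[:, 2]
    s = r + g + b
    relative = float(np.where(s > 0, r / np.where(s > 0, s, 1.0), 0.0).sum())
    rg = float((r - g).mean())
    rb = float((r - b).mean())
    hue = hue_degrees(pixels, chroma_floor=chroma_floor)
    defined = ~np.isnan(hue)
    red = float((_in_band(hue[defined], red_band)).sum() / n)
    return RednessScores(relative, rg, rb, red, n)


def score_batch(
    records: pd.DataFrame,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
    red_band: tuple[float, float] = DEFAULT_RED_BAND,
    chroma_floor: float = DEFAULT_CHROMA_FLOOR,
    gamma: float = 1.0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Score every record in a metadata table with image and mask paths.

    Returns (scores, failures): one score row per readable record with all
    metadata columns preserved; per-record failures are collected, not
    raised, so one corrupt image does not abort the batch.
    """
    rows, failures = [], []
    for _, rec in records.iterrows():
        try:
            img = load_image(rec["image_path"], gamma=gamma)
            mask = load_mask(rec["mask_path"]) if pd.notna(rec.get("mask_path")) else None
            roi = build_roi(img, mask, saturation_threshold=saturation_threshold)
            scores = score(img, roi, red_band=red_band, chroma_floor=chroma_floor)
            row = rec.to_dict()
            row.update(scores.as_dict())
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 — per-record isolation is the contract
            failures.append({"record_id": rec.get("record_id"), "error": str(exc)})
    if rows:
        table = pd.DataFrame(rows)
    else:
        columns = list(records.columns) + list(METRIC_NAMES) + ["n_pixels"]
        table = pd.DataFrame(columns=columns)
    return table, failures
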
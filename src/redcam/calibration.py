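"""White balance and color-correction-matrix estimation from chart patches.

One calibration model is fitted per (camera, lighting) pair: diagonal
white-balance gains anchored on a neutral chart patch, followed by a 3×3
color-correction matrix (optionally 3×4 affine) fitted by unweighted least
squares in linear RGB over the chart's patch means.  For any noiseless
linear camera whose forward model is a single invertible matrix, this
recovers the exact inverse; spatially varying effects such as vignetting
are deliberately outside what a single matrix can correct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CalibrationError
from .image import LinearImage
from .scene import ChartDefinition

__all__ = [
    "PatchMeasurement",
    "CalibrationModel",
    "measure_patches",
    "estimate_white_balance",
    "estimate_ccm",
    "apply_calibration",
    "calibrate_from_chart",
]

DEFAULT_SATURATION_THRESHOLD = 0.99
DEFAULT_BORDER_MARGIN = 0.2


@dataclass
class PatchMeasurement:
    """Observed vs. reference linear RGB for one chart patch."""

    patch_index: int
    measured_rgb: np.ndarray
    reference_rgb: np.ndarray
    saturated_fraction: float = 0.0
    flagged: bool = False  # >50% of interior pixels saturated


@dataclass
class CalibrationModel:
    """Estimated white-balance gains + color-correction matrix."""

    wb_gains: np.ndarray
    ccm: np.ndarray  # 3×3
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    residual_rmse: float = 0.0
    camera_id: str = ""
    lighting_id: str = ""

    def __post_init__(self) -> None:
        self.wb_gains = np.asarray(self.wb_gains, dtype=float)
        self.ccm = np.asarray(self.ccm, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        if np.any(self.wb_gains <= 0):
            raise CalibrationError("white-balance gains must be positive")

    def transform(self, rgb: np.ndarray) -> np.ndarray:
        """CCM · (wb ∘ rgb) + offset for an (..., 3) array, no clipping."""
        return np.einsum("ij,...j->...i", self.ccm, rgb * self.wb_gains) + self.offset

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "wb_gains": self.wb_gains.tolist(),
            "ccm": self.ccm.tolist(),  # row-major 3×3
            "offset": self.offset.tolist(),
            "residual_rmse": self.residual_rmse,
            "camera_id": self.camera_id,
            "lighting_id": self.lighting_id,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationModel":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else str(source))
        return cls(
            wb_gains=np.array(payload["wb_gains"]),
            ccm=np.array(payload["ccm"]),
            offset=np.array(payload.get("offset", [0.0, 0.0, 0.0])),
            residual_rmse=float(payload["residual_rmse"]),
            camera_id=payload.get("camera_id", ""),
            lighting_id=payload.get("lighting_id", ""),
        )


def measure_patches(
    chart_image: LinearImage | np.ndarray,
    chart: ChartDefinition,
    border_margin: float = DEFAULT_BORDER_MARGIN,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
) -> list[PatchMeasurement]:
    """Per-patch interior mean RGB paired with the chart's reference values.

    The interior excludes a border margin (default 20% of the patch size on
    each side).  Pixels with any channel at or above the saturation
    threshold are excluded from the mean; a patch whose interior is more
    than half saturated is flagged (its mean falls back to all interior
    pixels so a value is still reported).
    """
    if hasattr(chart_image, "rgb"):
        rgb = chart_image.rgb
    elif hasattr(chart_image, "reflectance"):
        rgb = chart_image.reflectance
    else:
        rgb = np.asarray(chart_image)
    h, w = rgb.shape[:2]
    if h % chart.n_rows or w % chart.n_cols:
        raise CalibrationError(
            f"image {h}×{w} does not tile the {chart.n_rows}×{chart.n_cols} chart layout"
        )
    ph, pw = h // chart.n_rows, w // chart.n_cols
    my, mx = int(round(border_margin * ph)), int(round(border_margin * pw))
    my, mx = min(my, (ph - 1) // 2), min(mx, (pw - 1) // 2)

    measurements = []
    for k in range(chart.n_rows * chart.n_cols):
        r, c = divmod(k, chart.n_cols)
        interior = rgb[r * ph + my : (r + 1) * ph - my, c * pw + mx : (c + 1) * pw - mx]
        pixels = interior.reshape(-1, 3)
        saturated = (pixels >= saturation_threshold).any(axis=1)
        sat_frac = float(saturated.mean())
        if sat_frac > 0.5:
            measured = pixels.mean(axis=0)
            flagged = True
        else:
            measured = pixels[~saturated].mean(axis=0)
            flagged = False
        measurements.append(
            PatchMeasurement(
                patch_index=k,
                measured_rgb=measured,
                reference_rgb=chart.patch_colors[k].copy(),
                saturated_fraction=sat_frac,
                flagged=flagged,
            )
        )
    return measurements


def estimate_white_balance(
    measurements: list[PatchMeasurement], neutral_patch_index: int
) -> np.ndarray:
    """Per-channel gains g_c = reference_c / measured_c at the neutral patch."""
    neutral = next(
        (m for m in measurements if m.patch_index == neutral_patch_index), None
    )
    if neutral is None:
        raise CalibrationError(f"no measurement for neutral patch {neutral_patch_index}")
    if neutral.flagged:
        raise CalibrationError("neutral patch is saturated; white balance impossible")
    if np.any(neutral.measured_rgb <= 0):
        raise CalibrationError("neutral patch has a zero channel; white balance impossible")
    return neutral.reference_rgb / neutral.measured_rgb


def estimate_ccm(
    measurements: list[PatchMeasurement],
    wb_gains: np.ndarray | None = None,
    affine: bool = False,
    camera_id: str = "",
    lighting_id: str = "",
) -> CalibrationModel:
    """Least-squares fit of reference = CCM · (wb ∘ measured) (+ offset).

    Flagged (saturated) patches are excluded from the fit.  The stored
    ``residual_rmse`` is the root-mean-square channel residual over the
    fitted patches.
    """
    wb = np.ones(3) if wb_gains is None else np.asarray(wb_gains, dtype=float)
    usable = [m for m in measurements if not m.flagged]
    min_patches = 5 if affine else 4
    if len(usable) < min_patches:
        raise CalibrationError(
            f"need at least {min_patches} unsaturated patches, have {len(usable)}"
        )
    x = np.array([m.measured_rgb for m in usable]) * wb
    y = np.array([m.reference_rgb for m in usable])
    design = np.hstack([x, np.ones((len(x), 1))]) if affine else x
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise CalibrationError("chart patches are collinear; CCM fit is rank-deficient")
    ccm = coef[:3].T
    offset = coef[3] if affine else np.zeros(3)
    residuals = design @ coef - y
    rmse = float(np.sqrt(np.mean(residuals**2)))
    return CalibrationModel(
        wb_gains=wb,
        ccm=ccm,
        offset=offset,
        residual_rmse=rmse,
        camera_id=camera_id,
        lighting_id=lighting_id,
    )


def apply_calibration(
    image: LinearImage,
    model: CalibrationModel,
    camera_id: str | None = None,
    lighting_id: str | None = None,
    force: bool = False,
) -> LinearImage:
    """Apply a calibration model per pixel and clip the result to [0, 1].

    If the image's (camera, lighting) identity is supplied it must match
    the model's, unless ``force`` is given.  The ROI mask is unchanged.
    """
    if not force:
        for given, expected, name in (
            (camera_id, model.camera_id, "camera"),
            (lighting_id, model.lighting_id, "lighting"),
        ):
            if given is not None and expected and given != expected:
                raise CalibrationError(
                    f"{name} mismatch: image is {given!r}, model is {expected!r}"
                )
    out = np.clip(model.transform(image.rgb), 0.0, 1.0)
    return LinearImage(rgb=out, roi_mask=image.roi_mask)


def calibrate_from_chart(
    chart_image: LinearImage | np.ndarray,
    chart: ChartDefinition,
    affine: bool = False,
    camera_id: str = "",
    lighting_id: str = "",
    border_margin: float = DEFAULT_BORDER_MARGIN,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
) -> CalibrationModel:
    """Convenience wrapper: measure patches, white balance, fit the CCM."""
    measurements = measure_patches(
        chart_image, chart, border_margin=border_margin,
        saturation_threshold=saturation_threshold,
    )
    wb = estimate_white_balance(measurements, chart.neutral_patch_index)
    return estimate_ccm(
        measurements, wb, affine=affine, camera_id=camera_id, lighting_id=lighting_id
    )
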
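"""Synthetic color charts, conjunctiva scenes, camera observations and graders.

This module generates the ground truth that a real slit-lamp photography
study cannot provide: ideal linear-light reflectance scenes (a 24-patch
color chart and whitish sclera crossed by a red vessel network of known
coverage), a parametric forward model of a smartphone camera looking
through a slit lamp (channel mixing, illuminant color cast, intensity
level, vignetting, peripheral hue distortion, sensor noise, clipping), and
simulated clinicians who grade redness on the Efron scale with perfect
color constancy — their grades depend only on the true vessel coverage,
never on the imaging condition.

Every generator is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage.draw import disk
from skimage.transform import resize

from .errors import ConfigurationError, GenerationError
from .image import LinearImage

__all__ = [
    "ChartDefinition",
    "SceneTruth",
    "CameraProfile",
    "GraderProfile",
    "StudyDesign",
    "Acquisition",
    "StudyData",
    "default_chart",
    "default_camera_profiles",
    "default_graders",
    "repeatability_graders",
    "identity_profile",
    "render_chart",
    "render_eye",
    "apply_camera",
    "simulate_graders",
    "generate_study",
]

# Plausible test-stable scene colors (linear RGB); tests assert metric
# relationships, never these absolute values.
SCLERA_COLOR = (0.92, 0.90, 0.86)
VESSEL_COLOR = (0.62, 0.15, 0.15)
IRIS_COLOR = (0.26, 0.30, 0.34)
EYELID_COLOR = (0.66, 0.50, 0.40)


@dataclass
class ChartDefinition:
    """A 24-patch color reference chart laid out on a rows×cols grid."""

    patch_colors: np.ndarray  # (24, 3) linear RGB ground truth in [0, 1]
    neutral_patch_index: int
    n_rows: int = 4
    n_cols: int = 6

    def __post_init__(self) -> None:
        self.patch_colors = np.asarray(self.patch_colors, dtype=float)
        if self.patch_colors.shape != (24, 3):
            raise ConfigurationError(
                f"chart needs exactly 24 RGB patches, got {self.patch_colors.shape}"
            )
        if self.n_rows * self.n_cols != 24:
            raise ConfigurationError("chart layout must tile exactly 24 patches")
        if np.any(self.patch_colors < 0) or np.any(self.patch_colors > 1):
            raise ConfigurationError("chart patch values must lie in [0, 1]")
        neutral = self.patch_colors[self.neutral_patch_index]
        if not np.allclose(neutral, neutral[0]):
            raise ConfigurationError("neutral patch must have R = G = B")


def default_chart() -> ChartDefinition:
    """Built-in 24-patch fixture: 18 chromatic patches + 6 neutrals.

    The values are generic (not the proprietary ColorChecker coordinates);
    real chart values can be supplied through :class:`ChartDefinition`.
    The neutral row ends the chart and includes an exact mid-gray used as
    the white-balance anchor.
    """
    colors = np.array(
        [
            # row 1 — natural tones
            (0.40, 0.22, 0.15), (0.75, 0.55, 0.45), (0.25, 0.35, 0.60),
            (0.20, 0.35, 0.15), (0.45, 0.45, 0.70), (0.30, 0.70, 0.60),
            # row 2 — saturated intermediates
            (0.80, 0.40, 0.10), (0.20, 0.25, 0.65), (0.70, 0.20, 0.25),
            (0.30, 0.12, 0.40), (0.55, 0.75, 0.15), (0.85, 0.60, 0.10),
            # row 3 — primaries and secondaries
            (0.10, 0.15, 0.55), (0.15, 0.55, 0.20), (0.70, 0.12, 0.10),
            (0.88, 0.78, 0.05), (0.70, 0.20, 0.55), (0.05, 0.50, 0.70),
            # row 4 — neutral ramp (mid-gray at index 20)
            (0.90, 0.90, 0.90), (0.72, 0.72, 0.72), (0.50, 0.50, 0.50),
            (0.36, 0.36, 0.36), (0.22, 0.22, 0.22), (0.10, 0.10, 0.10),
        ]
    )
    return ChartDefinition(patch_colors=colors, neutral_patch_index=20)


@dataclass
class SceneTruth:
    """An ideal reflectance scene before any camera touches it."""

    reflectance: np.ndarray  # (H, W, 3) linear RGB in [0, 1]
    roi_mask: np.ndarray | None = None  # eye scenes only
    true_redness: float | None = None  # achieved vessel coverage fraction
    scene_id: str = ""
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if np.any(self.reflectance < 0) or np.any(self.reflectance > 1):
            raise GenerationError("scene reflectance must lie in [0, 1]")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)


@dataclass
class CameraProfile:
    """Parametric forward model of one camera under one lighting condition.

    Observation model (applied in this order to reflectance ``s``):
    geometric magnification (central crop + resample) and radial hue
    rotation, then per-pixel ``V(x, y) · lighting_scale · G · M · s`` with
    ``M`` the channel-mixing matrix, ``G = diag(illuminant_gains)`` and
    ``V`` a radial vignette normalized to 1 at center, then additive
    Gaussian noise, gamma encoding and clipping to ``[0, clip_level]``.
    """

    mixing_matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    illuminant_gains: np.ndarray = field(default_factory=lambda: np.ones(3))
    lighting_scale: float = 1.0
    vignette_strength: float = 0.0
    peripheral_hue_shift: float = 0.0  # degrees per unit normalized radius
    gamma: float = 1.0  # encoding exponent; 1 = linear (raw) output
    noise_sd: float = 0.0
    clip_level: float = 1.0
    camera_id: str = ""
    lighting_id: str = ""

    def __post_init__(self) -> None:
        self.mixing_matrix = np.asarray(self.mixing_matrix, dtype=float)
        self.illuminant_gains = np.asarray(self.illuminant_gains, dtype=float)
        if self.mixing_matrix.shape != (3, 3):
            raise ConfigurationError("mixing_matrix must be 3×3")
        cond = np.linalg.cond(self.mixing_matrix)
        if not np.isfinite(cond) or cond > 1e8:
            raise ConfigurationError("mixing_matrix must be invertible")
        if self.lighting_scale <= 0:
            raise ConfigurationError("lighting_scale must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.gamma <= 0:
            raise ConfigurationError("gamma must be positive")

    @property
    def color_matrix(self) -> np.ndarray:
        """Combined linear color transform lighting_scale · G · M."""
        return self.lighting_scale * np.diag(self.illuminant_gains) @ self.mixing_matrix


def identity_profile(**overrides) -> CameraProfile:
    """A camera that observes the scene exactly as it is."""
    return CameraProfile(**overrides)


@dataclass
class GraderProfile:
    """One simulated clinician grading on the Efron scale (0–4, step 0.1)."""

    bias: float = 0.0
    noise_sd: float = 0.0
    scale_min: float = 0.0
    scale_max: float = 4.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("grader noise_sd must be non-negative")
        if self.scale_max <= self.scale_min or self.step <= 0:
            raise ConfigurationError("invalid grading scale")


def default_graders() -> list[GraderProfile]:
    """Three deterministic clinicians with distinct additive biases."""
    return [GraderProfile(bias=b) for b in (-0.10, 0.0, 0.15)]


def repeatability_graders() -> list[GraderProfile]:
    """Three clinicians with grading noise, for repeatability analyses.

    Noise standard deviations 0.11 / 0.22 / 0.27 Efron units reproduce the
    per-clinician within-subject repeatability reported for human graders
    of bulbar redness on this scale.
    """
    return [
        GraderProfile(bias=-0.10, noise_sd=0.11),
        GraderProfile(bias=0.0, noise_sd=0.22),
        GraderProfile(bias=0.15, noise_sd=0.27),
    ]


@dataclass
class StudyDesign:
    """The factorial acquisition design of the simulated study.

    The default enumerates 3 cameras × 2 lighting levels × 2 magnifications
    × 2 replicates = 24 acquisition cells per subject, and with 2
    processing arms and 4 subjects, 192 image records in total.
    """

    subjects: tuple[str, ...] = ("S1", "S2", "S3", "S4")
    cameras: tuple[str, ...] = ("cam1", "cam2", "cam3")
    lighting_levels: tuple[str, ...] = ("high", "low")
    magnifications: tuple[float, ...] = (6.0, 10.0)
    replicates: int = 2
    processing_arms: tuple[str, ...] = ("pre", "post")
    redness_range: tuple[float, float] = (0.05, 0.6)
    scene_size: int = 192

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        lo, hi = self.redness_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError("redness_range must lie within [0, 1]")

    @property
    def n_acquisition_cells_per_subject(self) -> int:
        return (
            len(self.cameras)
            * len(self.lighting_levels)
            * len(self.magnifications)
            * self.replicates
        )

    @property
    def n_image_records(self) -> int:
        return (
            self.n_acquisition_cells_per_subject
            * len(self.processing_arms)
            * len(self.subjects)
        )


def default_camera_profiles(
    cameras: Sequence[str] = ("cam1", "cam2", "cam3"),
    lighting_levels: Sequence[str] = ("high", "low"),
    *,
    vignette_strength: float = 0.0,
    peripheral_hue_shift: float = 0.0,
    noise_sd: float = 0.0,
    gamma: float = 1.0,
) -> dict[tuple[str, str], CameraProfile]:
    """One profile per (camera, lighting) pair.

    Each camera has its own near-diagonal channel-mixing matrix (distinct
    sensor spectral responses); each lighting level has its own illuminant
    color cast and intensity scale shared across cameras (the slit-lamp
    lamp is the same physical source). Defaults are noiseless and
    vignette-free; degradations are opt-in keyword arguments.
    """
    # Per-camera crosstalk differs, but all three share the green-dominant
    # channel sensitivity typical of raw Bayer CMOS output before white
    # balance — uncalibrated raw frames lean green/desaturated in the same
    # direction on every phone.
    sensitivity = np.diag([0.94, 1.06, 0.98])
    # per-camera red-response factors: phones differ most in how strongly
    # their red channel responds, which dominates between-camera redness
    # differences in uncalibrated images
    red_response = (0.94, 1.04, 0.90)
    mixings = [
        np.diag([red_response[0], 1.0, 1.0]) @ sensitivity
        @ np.array([[0.92, 0.06, 0.02], [0.05, 0.90, 0.05], [0.02, 0.08, 0.90]]),
        np.diag([red_response[1], 1.0, 1.0]) @ sensitivity
        @ np.array([[0.88, 0.09, 0.03], [0.03, 0.93, 0.04], [0.04, 0.05, 0.91]]),
        np.diag([red_response[2], 1.0, 1.0]) @ sensitivity
        @ np.array([[0.96, 0.03, 0.01], [0.08, 0.86, 0.06], [0.01, 0.05, 0.94]]),
    ]
    # Lighting levels act mainly as color-temperature casts: the halogen
    # slit-lamp source is warm at full power and warmer still when dimmed,
    # while smartphone auto-exposure largely equalizes mean image
    # brightness, leaving only a mild residual intensity difference in the
    # raw signal.
    lighting_params = {
        "high": (np.array([1.08, 1.00, 0.84]), 1.00),  # bright, warm
        "low": (np.array([1.16, 1.00, 0.70]), 0.92),  # dim, much warmer
    }
    profiles: dict[tuple[str, str], CameraProfile] = {}
    for i, cam in enumerate(cameras):
        for light in lighting_levels:
            gains, scale = lighting_params.get(light, (np.ones(3), 1.0))
            profiles[(cam, light)] = CameraProfile(
                mixing_matrix=mixings[i % len(mixings)],
                illuminant_gains=gains,
                lighting_scale=scale,
                vignette_strength=vignette_strength,
                peripheral_hue_shift=peripheral_hue_shift,
                noise_sd=noise_sd,
                gamma=gamma,
                camera_id=cam,
                lighting_id=light,
            )
    return profiles


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def render_chart(chart: ChartDefinition, patch_px: int = 32) -> SceneTruth:
    """Render the chart as a flat reflectance image, one block per patch."""
    if patch_px < 1:
        raise ConfigurationError("patch_px must be >= 1")
    grid = chart.patch_colors.reshape(chart.n_rows, chart.n_cols, 3)
    reflectance = np.kron(grid, np.ones((patch_px, patch_px))[:, :, None])
    return SceneTruth(reflectance=reflectance, scene_id="chart")


def _eye_geometry(size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean masks for the iris disc, eyelid bands and the usable ROI."""
    yy, xx = np.mgrid[0:size, 0:size]
    # temporal view: iris bulges in from the left edge
    iris = (yy - size / 2) ** 2 + (xx - 0.0) ** 2 < (0.38 * size) ** 2
    lid = int(round(0.12 * size))
    eyelids = np.zeros((size, size), dtype=bool)
    eyelids[:lid, :] = True
    eyelids[size - lid :, :] = True
    roi = ~iris & ~eyelids
    return iris, eyelids, roi


def render_eye(
    subject_id: str,
    true_redness: float,
    size: int = 192,
    seed: int = 0,
    *,
    sclera_color: Sequence[float] = SCLERA_COLOR,
    vessel_color: Sequence[float] = VESSEL_COLOR,
    coverage_tol: float = 0.02,
    max_walks: int = 8000,
) -> SceneTruth:
    """Draw a conjunctiva scene with a controlled vessel-coverage fraction.

    Vessels are seeded random-walk polylines rasterized in the vessel
    color until the fraction of ROI pixels they cover is within
    ``coverage_tol`` of ``true_redness``.  Severity is expressed mainly as
    vasodilation: the walk width grows with the target coverage (a redder
    eye has wider vessels, not proportionally more of them), with thin
    top-up walks for fine coverage control.  The ROI excludes an iris disc
    and two eyelid bands by construction.
    """
    if not 0.0 <= true_redness <= 1.0:
        raise GenerationError("true_redness must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    iris, eyelids, roi = _eye_geometry(size)
    n_roi = int(roi.sum())

    vessel_mask = np.zeros((size, size), dtype=bool)
    n_walks = 0
    target = true_redness
    coverage = 0.0
    # dilated-vessel width (pixels) for this severity, scaled to scene size
    base_width = (0.8 + 3.2 * true_redness) * size / 192.0
    roi_rows, roi_cols = np.nonzero(roi)
    while coverage < target - 0.25 * coverage_tol:
        if n_walks >= max_walks:
            raise GenerationError(
                f"vessel coverage {coverage:.3f} unreachable for target {target:.3f}"
            )
        n_walks += 1
        # switch to thin short walks for the final approach to the target
        fine = (target - coverage) < 0.01
        width = max(0.8, base_width if not fine else 0.8)
        n_steps = int(rng.integers(8, 16)) if fine else int(rng.integers(30, 60))
        i = rng.integers(n_roi)
        y, x = float(roi_rows[i]), float(roi_cols[i])
        angle = rng.uniform(0, 2 * np.pi)
        for _ in range(n_steps):
            rr, cc = disk((y, x), width, shape=(size, size))
            vessel_mask[rr, cc] = True
            angle += rng.normal(0, 0.35)
            y += 1.6 * np.sin(angle)
            x += 1.6 * np.cos(angle)
            if not (0 <= y < size and 0 <= x < size):
                break
        coverage = vessel_mask[roi].sum() / n_roi

    reflectance = np.empty((size, size, 3))
    reflectance[:] = np.asarray(sclera_color)
    reflectance[vessel_mask] = np.asarray(vessel_color)
    reflectance[iris] = np.asarray(IRIS_COLOR)
    reflectance[eyelids] = np.asarray(EYELID_COLOR)
    achieved = float(vessel_mask[roi].sum() / n_roi)
    return SceneTruth(
        reflectance=reflectance,
        roi_mask=roi,
        true_redness=achieved,
        scene_id=f"eye_{subject_id}",
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# camera forward model
# ---------------------------------------------------------------------------


def _normalized_radius(h: int, w: int) -> np.ndarray:
    """Radial distance from image center, 1.0 at the corners."""
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot((yy - cy) / max(cy, 1e-9), (xx - cx) / max(cx, 1e-9))
    return r / np.sqrt(2.0)


def _rotate_hue(rgb: np.ndarray, angle_deg: np.ndarray) -> np.ndarray:
    """Rotate pixel colors about the gray axis by a per-pixel angle.

    Rotation about (1,1,1)/sqrt(3) shifts hue while preserving the channel
    sum, which is how peripheral chromatic distortion behaves to first
    order.
    """
    theta = np.deg2rad(angle_deg)[..., None]
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    k = np.full(3, 1.0 / np.sqrt(3.0))
    cross = np.stack(
        [
            rgb[..., 2] - rgb[..., 1],
            rgb[..., 0] - rgb[..., 2],
            rgb[..., 1] - rgb[..., 0],
        ],
        axis=-1,
    ) / np.sqrt(3.0)
    dot = (rgb @ k)[..., None]
    return rgb * cos_t + cross * sin_t + k * dot * (1.0 - cos_t)


def _magnify(arr: np.ndarray, magnification: float, *, order: int) -> np.ndarray:
    """Central crop by 1/magnification, then resample to the original size."""
    h, w = arr.shape[:2]
    ch = max(2, int(round(h / magnification)))
    cw = max(2, int(round(w / magnification)))
    y0, x0 = (h - ch) // 2, (w - cw) // 2
    cropped = arr[y0 : y0 + ch, x0 : x0 + cw]
    out = resize(
        cropped.astype(float),
        (h, w) + arr.shape[2:],
        order=order,
        anti_aliasing=False,
        preserve_range=True,
    )
    return out


def apply_camera(
    scene: SceneTruth,
    profile: CameraProfile,
    magnification: float = 1.0,
    seed: int | None = None,
) -> LinearImage:
    """Image a scene through a camera profile at a given magnification.

    An identity profile at magnification 1 returns the scene exactly.
    """
    rgb = scene.reflectance
    mask = scene.roi_mask
    if magnification != 1.0:
        rgb = np.clip(_magnify(rgb, magnification, order=1), 0.0, 1.0)
        if mask is not None:
            mask = _magnify(mask.astype(float), magnification, order=0) > 0.5
    h, w = rgb.shape[:2]
    if profile.peripheral_hue_shift != 0.0:
        r = _normalized_radius(h, w)
        rgb = _rotate_hue(rgb, profile.peripheral_hue_shift * r)
    a = profile.color_matrix
    if not np.array_equal(a, np.eye(3)):
        rgb = np.einsum("ij,hwj->hwi", a, rgb)
    else:
        rgb = rgb * 1.0
    if profile.vignette_strength != 0.0:
        r = _normalized_radius(h, w)
        v = np.clip(1.0 - profile.vignette_strength * r**2, 0.0, 1.0)
        rgb = rgb * v[..., None]
    if profile.noise_sd > 0:
        rng = np.random.default_rng(seed)
        rgb = rgb + rng.normal(0.0, profile.noise_sd, size=rgb.shape)
    if profile.gamma != 1.0:
        rgb = np.clip(rgb, 0.0, None) ** (1.0 / profile.gamma)
    rgb = np.clip(rgb, 0.0, profile.clip_level)
    return LinearImage(rgb=rgb, roi_mask=None if mask is None else mask)


# ---------------------------------------------------------------------------
# graders
# ---------------------------------------------------------------------------


def simulate_graders(
    true_redness: float,
    graders: Sequence[GraderProfile],
    seed: int | None = None,
) -> list[float]:
    """Grade a scene on the Efron scale, emulating human color constancy.

    Grades are a function of the true vessel coverage only — never of the
    camera, lighting, magnification or processing arm — plus per-grader
    bias and noise, clamped to the scale and rounded to its step.
    """
    if len(graders) == 0:
        raise ConfigurationError("at least one grader is required")
    rng = np.random.default_rng(seed)
    grades = []
    for g in graders:
        raw = 4.0 * true_redness + g.bias + g.noise_sd * rng.normal()
        clamped = min(max(raw, g.scale_min), g.scale_max)
        grades.append(float(np.round(clamped / g.step) * g.step))
    return grades


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------


@dataclass
class Acquisition:
    """One photograph: a (subject, camera, lighting, magnification,
    replicate) cell realized through the camera forward model."""

    index: int
    subject: str
    camera: str
    lighting: str
    magnification: float
    replicate: int
    image: LinearImage
    scene: SceneTruth
    seed: int


@dataclass
class StudyData:
    """Everything the downstream pipeline needs: chart shots per
    (camera, lighting) pair, per-subject ground-truth scenes, the raw
    acquisitions and the 192-row record metadata table (one row per
    acquisition × processing arm, Efron grades attached)."""

    design: StudyDesign
    chart: ChartDefinition
    chart_images: dict[tuple[str, str], LinearImage]
    scenes: dict[str, SceneTruth]
    acquisitions: list[Acquisition]
    records: "object"  # pandas.DataFrame; typed loosely to keep imports light
    seed: int


def generate_study(
    design: StudyDesign,
    profiles: Mapping[tuple[str, str], CameraProfile],
    graders: Sequence[GraderProfile],
    seed: int = 0,
    chart: ChartDefinition | None = None,
    chart_patch_px: int = 24,
) -> StudyData:
    """Generate the full synthetic study for one master seed.

    Per subject, a single true redness is drawn once (uniform over the
    design's redness range) and held fixed across all conditions; every
    acquisition, grade draw and the condition randomization order derive
    deterministic sub-seeds from the master seed.
    """
    import pandas as pd

    for cam, light in itertools.product(design.cameras, design.lighting_levels):
        if (cam, light) not in profiles:
            raise ConfigurationError(f"missing camera profile for {(cam, light)}")
    chart = chart or default_chart()

    master = np.random.default_rng(seed)

    def sub_seed() -> int:
        return int(master.integers(2**31))

    # chart observations at magnification 1 (the chart fills the frame)
    chart_scene = render_chart(chart, patch_px=chart_patch_px)
    chart_images = {
        key: apply_camera(chart_scene, profiles[key], 1.0, seed=sub_seed())
        for key in sorted(profiles)
        if key[0] in design.cameras and key[1] in design.lighting_levels
    }

    scenes: dict[str, SceneTruth] = {}
    for subject in design.subjects:
        lo, hi = design.redness_range
        target = float(master.uniform(lo, hi))
        scenes[subject] = render_eye(
            subject, target, size=design.scene_size, seed=sub_seed()
        )

    acquisitions: list[Acquisition] = []
    cells = list(
        itertools.product(
            design.subjects,
            design.cameras,
            design.lighting_levels,
            design.magnifications,
            range(1, design.replicates + 1),
        )
    )
    for idx, (subject, cam, light, mag, rep) in enumerate(cells):
        acq_seed = sub_seed()
        image = apply_camera(scenes[subject], profiles[(cam, light)], mag, seed=acq_seed)
        acquisitions.append(
            Acquisition(idx, subject, cam, light, mag, rep, image, scenes[subject], acq_seed)
        )

    order = master.permutation(len(acquisitions))  # randomized condition schedule

    rows = []
    for acq in acquisitions:
        for arm in design.processing_arms:
            grades = simulate_graders(acq.scene.true_redness, graders, seed=sub_seed())
            row = {
                "record_id": (
                    f"{acq.subject}_{acq.camera}_{acq.lighting}"
                    f"_m{acq.magnification:g}_r{acq.replicate}_{arm}"
                ),
                "subject": acq.subject,
                "camera": acq.camera,
                "lighting": acq.lighting,
                "magnification": acq.magnification,
                "replicate": acq.replicate,
                "processing_arm": arm,
                "true_redness": acq.scene.true_redness,
                "acquisition_index": acq.index,
                "acquisition_order": int(order[acq.index]),
            }
            for j, g in enumerate(grades, start=1):
                row[f"grade_rater{j}"] = g
            rows.append(row)
    records = pd.DataFrame(rows)
    return StudyData(
        design=design,
        chart=chart,
        chart_images=chart_images,
        scenes=scenes,
        acquisitions=acquisitions,
        records=records,
        seed=seed,
    )
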
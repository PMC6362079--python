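"""End-to-end orchestration: generate → calibrate → score → analyze → report.

`run_study` executes the whole synthetic replication from one config and
master seed: it generates the factorial study, fits one calibration model
per (camera, lighting) pair from that pair's chart shot, applies it to the
post-calibration arm, scores all records with the four redness metrics,
and runs the agreement/correlation/ANOVA analysis layer.  Everything is
deterministic given the master seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationModel, apply_calibration, calibrate_from_chart
from .errors import RenderError
from .image import save_image, save_mask
from .metrics import (
    DEFAULT_CHROMA_FLOOR,
    DEFAULT_RED_BAND,
    DEFAULT_SATURATION_THRESHOLD,
    METRIC_NAMES,
    build_roi,
    score,
)
from .scene import (
    CameraProfile,
    ChartDefinition,
    GraderProfile,
    StudyData,
    StudyDesign,
    default_camera_profiles,
    default_chart,
    default_graders,
    generate_study,
)
from .stats import AnovaTable, bland_altman, pearson, rm_anova, within_subject_sd

__all__ = ["RunConfig", "StudyBundle", "run_study", "render_report", "analyze_scores"]

FACTORS = ["processing_arm", "camera", "lighting", "magnification"]


@dataclass
class RunConfig:
    """Validated configuration for one full synthetic study run."""

    design: StudyDesign = field(default_factory=StudyDesign)
    profiles: dict[tuple[str, str], CameraProfile] = field(default_factory=dict)
    graders: list[GraderProfile] = field(default_factory=default_graders)
    chart: ChartDefinition = field(default_factory=default_chart)
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD
    red_band: tuple[float, float] = DEFAULT_RED_BAND
    chroma_floor: float = DEFAULT_CHROMA_FLOOR
    affine_ccm: bool = False
    alpha: float = 0.05
    seed: int = 0
    write_images: bool = False

    def __post_init__(self) -> None:
        if not self.profiles:
            self.profiles = default_camera_profiles(
                self.design.cameras, self.design.lighting_levels
            )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = self.design
        return {
            "seed": self.seed,
            "design": {
                "subjects": list(d.subjects),
                "cameras": list(d.cameras),
                "lighting_levels": list(d.lighting_levels),
                "magnifications": list(d.magnifications),
                "replicates": d.replicates,
                "processing_arms": list(d.processing_arms),
                "redness_range": list(d.redness_range),
                "scene_size": d.scene_size,
            },
            "profiles": {
                f"{cam}|{light}": {
                    "mixing_matrix": p.mixing_matrix.tolist(),
                    "illuminant_gains": p.illuminant_gains.tolist(),
                    "lighting_scale": p.lighting_scale,
                    "vignette_strength": p.vignette_strength,
                    "peripheral_hue_shift": p.peripheral_hue_shift,
                    "gamma": p.gamma,
                    "noise_sd": p.noise_sd,
                    "clip_level": p.clip_level,
                }
                for (cam, light), p in sorted(self.profiles.items())
            },
            "graders": [
                {"bias": g.bias, "noise_sd": g.noise_sd} for g in self.graders
            ],
            "chart": {
                "patch_colors": self.chart.patch_colors.tolist(),
                "neutral_patch_index": self.chart.neutral_patch_index,
                "n_rows": self.chart.n_rows,
                "n_cols": self.chart.n_cols,
            },
            "metrics": {
                "saturation_threshold": self.saturation_threshold,
                "red_band": list(self.red_band),
                "chroma_floor": self.chroma_floor,
            },
            "stats": {"alpha": self.alpha, "affine_ccm": self.affine_ccm},
            "write_images": self.write_images,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        dd = payload.get("design", {})
        design = StudyDesign(
            subjects=tuple(dd.get("subjects", StudyDesign.subjects)),
            cameras=tuple(dd.get("cameras", StudyDesign.cameras)),
            lighting_levels=tuple(dd.get("lighting_levels", StudyDesign.lighting_levels)),
            magnifications=tuple(dd.get("magnifications", StudyDesign.magnifications)),
            replicates=dd.get("replicates", 2),
            processing_arms=tuple(dd.get("processing_arms", ("pre", "post"))),
            redness_range=tuple(dd.get("redness_range", (0.05, 0.6))),
            scene_size=dd.get("scene_size", 192),
        )
        profiles = {}
        for key, pp in payload.get("profiles", {}).items():
            cam, light = key.split("|")
            profiles[(cam, light)] = CameraProfile(camera_id=cam, lighting_id=light, **pp)
        graders = [GraderProfile(**g) for g in payload.get("graders", [])]
        chart_d = payload.get("chart")
        chart = (
            ChartDefinition(
                patch_colors=np.array(chart_d["patch_colors"]),
                neutral_patch_index=chart_d["neutral_patch_index"],
                n_rows=chart_d.get("n_rows", 4),
                n_cols=chart_d.get("n_cols", 6),
            )
            if chart_d
            else default_chart()
        )
        metrics = payload.get("metrics", {})
        stats_opts = payload.get("stats", {})
        return cls(
            design=design,
            profiles=profiles,
            graders=graders or default_graders(),
            chart=chart,
            saturation_threshold=metrics.get("saturation_threshold", DEFAULT_SATURATION_THRESHOLD),
            red_band=tuple(metrics.get("red_band", DEFAULT_RED_BAND)),
            chroma_floor=metrics.get("chroma_floor", DEFAULT_CHROMA_FLOOR),
            affine_ccm=stats_opts.get("affine_ccm", False),
            alpha=stats_opts.get("alpha", 0.05),
            seed=payload.get("seed", 0),
            write_images=payload.get("write_images", False),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class StudyBundle:
    """All in-memory artifacts of one study run."""

    config: RunConfig
    study: StudyData
    models: dict[tuple[str, str], CalibrationModel]
    scores: pd.DataFrame
    anovas: dict[str, AnovaTable]
    correlations: pd.DataFrame
    camera_spread: pd.DataFrame
    camera_effect_by_arm: pd.DataFrame
    repeatability: dict
    agreement: dict
    manifest: dict


def _score_records(config: RunConfig, study: StudyData,
                   models: dict[tuple[str, str], CalibrationModel]) -> pd.DataFrame:
    rows = []
    for acq in study.acquisitions:
        images = {"pre": acq.image}
        if "post" in study.design.processing_arms:
            images["post"] = apply_calibration(
                acq.image, models[(acq.camera, acq.lighting)],
                camera_id=acq.camera, lighting_id=acq.lighting,
            )
        for arm in study.design.processing_arms:
            img = images[arm]
            roi = build_roi(img, saturation_threshold=config.saturation_threshold)
            s = score(img, roi, red_band=config.red_band, chroma_floor=config.chroma_floor)
            rows.append({"acquisition_index": acq.index, "processing_arm": arm, **s.as_dict()})
    scored = pd.DataFrame(rows)
    return study.records.merge(scored, on=["acquisition_index", "processing_arm"])


def analyze_scores(scores: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Run the full analysis layer on a long score table.

    Returns a dict with per-response ANOVA tables, the objective–subjective
    correlation table, per-rater repeatability, inter-rater agreement, and
    the between-camera spread per arm.
    """
    rater_cols = sorted(c for c in scores.columns if c.startswith("grade_rater"))
    scores = scores.copy()
    scores["grade_mean"] = scores[rater_cols].mean(axis=1)

    # factors with a single level in this design carry no variance to test
    factors = [f for f in FACTORS if scores[f].nunique() >= 2]
    anovas: dict[str, AnovaTable] = {}
    for metric in METRIC_NAMES:
        anovas[metric] = rm_anova(scores, dv=metric, within=factors)
    anovas["subjective"] = rm_anova(scores, dv=rater_cols[0], within=factors)
    anovas["subjective_mean"] = rm_anova(scores, dv="grade_mean", within=factors)

    # correlation table: all factors together, and by arm × camera
    corr_rows = []
    groupings = [("all", scores)] + [
        (f"{arm}:{cam}", g)
        for (arm, cam), g in scores.groupby(["processing_arm", "camera"], sort=True)
    ]
    for rater in rater_cols + ["grade_mean"]:
        for label, g in groupings:
            for metric in METRIC_NAMES:
                try:
                    r, p = pearson(g[metric], g[rater])
                except Exception:
                    r, p = np.nan, np.nan
                corr_rows.append(
                    {
                        "grouping": label,
                        "rater": rater,
                        "metric": metric,
                        "r": r,
                        "p": p,
                        "n": len(g),
                        "significant": bool(p < alpha) if np.isfinite(p) else False,
                    }
                )
    correlations = pd.DataFrame(corr_rows)

    # per-rater repeatability over replicate photographs of the same cell
    cell_cols = ["subject", "camera", "lighting", "magnification", "processing_arm"]
    repeatability = {}
    for rater in rater_cols:
        groups = [g[rater].to_numpy() for _, g in scores.groupby(cell_cols, sort=True)]
        try:
            repeatability[rater] = within_subject_sd(groups)
        except Exception:
            repeatability[rater] = None

    # inter-rater Bland–Altman over all records
    agreement = {}
    for a, b in itertools.combinations(rater_cols, 2):
        agreement[f"{a}_vs_{b}"] = bland_altman(scores[a], scores[b]).as_dict()

    # between-camera spread of each metric, per arm
    spread_rows = []
    for arm, g in scores.groupby("processing_arm", sort=True):
        cam_means = g.groupby("camera", sort=True)[list(METRIC_NAMES)].mean()
        for metric in METRIC_NAMES:
            spread_rows.append(
                {
                    "processing_arm": arm,
                    "metric": metric,
                    "between_camera_sd": float(cam_means[metric].std(ddof=1)),
                }
            )
    camera_spread = pd.DataFrame(spread_rows)

    # camera effect tested within each arm separately
    arm_rows = []
    for arm, g in scores.groupby("processing_arm", sort=True):
        for metric in METRIC_NAMES:
            tab = rm_anova(g, dv=metric, within=["camera"])
            row = tab.effect("camera")
            arm_rows.append(
                {
                    "processing_arm": arm,
                    "metric": metric,
                    "F": row["F"],
                    "p": row["p"],
                    "significant": row["p"] < alpha,
                }
            )
    camera_effect_by_arm = pd.DataFrame(arm_rows)

    return {
        "anovas": anovas,
        "correlations": correlations,
        "repeatability": repeatability,
        "agreement": agreement,
        "camera_spread": camera_spread,
        "camera_effect_by_arm": camera_effect_by_arm,
    }


def run_study(config: RunConfig, outdir: str | Path | None = None) -> StudyBundle:
    """Execute the full pipeline; write the output bundle if ``outdir`` given."""
    manifest: dict = {"seed": config.seed, "version": __version__, "stages": {}}

    def _stage(name):
        manifest["stages"][name] = "ok"

    try:
        stage = "generate"
        study = generate_study(
            config.design, config.profiles, config.graders,
            seed=config.seed, chart=config.chart,
        )
        _stage(stage)

        stage = "calibrate"
        models = {
            key: calibrate_from_chart(
                img, config.chart, affine=config.affine_ccm,
                camera_id=key[0], lighting_id=key[1],
                saturation_threshold=config.saturation_threshold,
            )
            for key, img in study.chart_images.items()
        }
        _stage(stage)

        stage = "score"
        scores = _score_records(config, study, models)
        _stage(stage)

        stage = "analyze"
        analysis = analyze_scores(scores, alpha=config.alpha)
        _stage(stage)
    except Exception:
        manifest["stages"][stage] = "failed"
        if outdir is not None:
            out = Path(outdir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["n_records"] = len(scores)
    manifest["n_acquisition_cells_per_subject"] = config.design.n_acquisition_cells_per_subject
    bundle = StudyBundle(
        config=config,
        study=study,
        models=models,
        scores=scores,
        anovas=analysis["anovas"],
        correlations=analysis["correlations"],
        camera_spread=analysis["camera_spread"],
        camera_effect_by_arm=analysis["camera_effect_by_arm"],
        repeatability=analysis["repeatability"],
        agreement=analysis["agreement"],
        manifest=manifest,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: StudyBundle, outdir: str | Path) -> None:
    """Serialize a bundle: CSV tables, JSON stats, config copy, manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.config.to_yaml(out / "config.yaml")
    meta_cols = [c for c in bundle.study.records.columns]
    records = bundle.study.records.copy()
    if bundle.config.write_images:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        paths = {}
        for acq in bundle.study.acquisitions:
            stem = f"acq{acq.index:03d}"
            save_image(img_dir / f"{stem}.tiff", acq.image)
            if acq.image.roi_mask is not None:
                save_mask(img_dir / f"{stem}_mask.png", acq.image.roi_mask)
            paths[acq.index] = (
                str(img_dir / f"{stem}.tiff"),
                str(img_dir / f"{stem}_mask.png"),
            )
        records["image_path"] = records["acquisition_index"].map(lambda i: paths[i][0])
        records["mask_path"] = records["acquisition_index"].map(lambda i: paths[i][1])
    records.to_csv(out / "metadata.csv", index=False)
    bundle.scores.to_csv(out / "scores.csv", index=False)
    for name, tab in bundle.anovas.items():
        tab.table.to_csv(out / f"anova_{name}.csv", index=False)
    bundle.correlations.to_csv(out / "correlations.csv", index=False)
    bundle.camera_spread.to_csv(out / "camera_spread.csv", index=False)
    bundle.camera_effect_by_arm.to_csv(out / "camera_effect_by_arm.csv", index=False)
    (out / "bland_altman.json").write_text(json.dumps(bundle.agreement, indent=2))
    (out / "repeatability.json").write_text(json.dumps(bundle.repeatability, indent=2))
    for key, model in bundle.models.items():
        model.to_json(out / f"calibration_{key[0]}_{key[1]}.json")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))
    (out / "report.txt").write_text(render_report(bundle))


def _stars(p: float, alpha: float) -> str:
    return "*" if np.isfinite(p) and p < alpha else ""


def render_report(bundle: StudyBundle) -> str:
    """Human-readable summary of the run (synthetic-data results)."""
    missing = [
        name
        for name, obj in [
            ("scores", bundle.scores),
            ("anovas", bundle.anovas),
            ("correlations", bundle.correlations),
        ]
        if obj is None or len(obj) == 0
    ]
    if missing:
        raise RenderError(f"cannot render report; missing tables: {missing}")
    alpha = bundle.config.alpha
    lines = [
        "SYNTHETIC-DATA STUDY REPORT",
        "(all results below are computed on simulated scenes and simulated",
        " graders; they characterize the pipeline, not real eyes)",
        "",
        f"records scored: {len(bundle.scores)}   "
        f"acquisition cells/subject: {bundle.config.design.n_acquisition_cells_per_subject}",
        "",
        "Repeatability (within-subject SD of replicate grades, per rater):",
    ]
    for rater, sw in bundle.repeatability.items():
        lines.append(f"  {rater}: {'n/a' if sw is None else f'{sw:.3f}'}")
    lines.append("")
    lines.append("Inter-rater 95% limits of agreement:")
    for pair, ba in bundle.agreement.items():
        lines.append(
            f"  {pair}: mean diff {ba['mean_diff']:+.3f}, "
            f"LoA [{ba['loa_low']:+.3f}, {ba['loa_high']:+.3f}] (n={ba['n']})"
        )
    lines.append("")
    lines.append("Objective–subjective Pearson correlations (rater 1):")
    c1 = bundle.correlations.query("rater == 'grade_rater1'")
    for label, g in c1.groupby("grouping", sort=True):
        cells = "  ".join(
            f"{row.metric}={row.r:.2f}{_stars(row.p, alpha)}" for row in g.itertuples()
        )
        lines.append(f"  {label:10s} {cells}")
    for name, tab in bundle.anovas.items():
        lines.append("")
        lines.append(f"Repeated-measures ANOVA — {name} ({len(tab.table)} effects):")
        for row in tab.table.itertuples():
            f_txt = "inf" if np.isinf(row.F) else f"{row.F:8.2f}"
            p_txt = "<0.001" if row.p < 0.001 else f"{row.p:.3f}"
            lines.append(
                f"  {row.effect:55s} F={f_txt} p={p_txt}{_stars(row.p, alpha)}"
            )
    lines.append("")
    lines.append("Between-camera spread of each metric (SD over camera means):")
    for row in bundle.camera_spread.itertuples():
        lines.append(
            f"  {row.processing_arm:4s} {row.metric:18s} {row.between_camera_sd:.6g}"
        )
    return "\n".join(lines) + "\n"
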
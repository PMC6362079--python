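# Methods

This note documents the models, defaults and numerical choices behind
`redcam`, and what the synthetic experiments do and do not demonstrate.

## Scene model

A conjunctiva scene is a linear-light RGB reflectance image in [0, 1]
with a binary region of interest (ROI). Geometry is fixed: an iris disc
bulging in from the left edge (temporal view, radius 0.38 of the image
side) and eyelid bands covering the top and bottom 12% are excluded from
the ROI by construction. The sclera is a near-neutral warm white,
(0.92, 0.90, 0.86); vessels are drawn in (0.62, 0.15, 0.15). Both are
configurable; no test depends on their absolute values, only on metric
relationships.

Vessels are seeded random-walk polylines rasterized until the fraction of
ROI pixels covered is within ±0.02 of the requested coverage
(`true_redness`). Severity is expressed mainly as **vasodilation**: the
stroke width grows with the target coverage (≈0.8 px at coverage 0.05 to
≈2.7 px at 0.6, at the default 192-px scene size) while the number of
walks stays roughly constant, with thin short "top-up" walks for the
final approach to the target. This mirrors the physiology of hyperaemia
(dilated vessels rather than proportionally more vessels) and keeps
vessel-boundary pixel counts — which drive the red-hue metric's response
to color distortions — comparable across subjects.

Per subject, one coverage value is drawn uniformly from [0.05, 0.6]
(healthy-to-moderate range; the upper end of the Efron scale is not
represented) and held fixed across all imaging conditions.

## Camera model

One profile per (camera, lighting) pair:

```
observed = clip( gamma_encode( V(x,y) · ℓ · G · M · s'(x,y) + noise ), 0, clip_level )
```

with `s'` the reflectance after central crop by 1/magnification,
resampling back to the original size (bilinear for the image, nearest for
the mask), and a radial hue rotation (degrees per unit normalized radius,
implemented as rotation about the gray axis, which preserves the channel
sum). `M` is the 3×3 channel-mixing matrix, `G` the illuminant gains, `ℓ`
the intensity scale, `V = max(0, 1 − v·r²)` the vignette normalized to 1
at center, noise additive Gaussian per channel (no shot-noise term — the
simplest model that supports the calibration-recovery experiments), and
gamma = 1 by default (raw, linear output; encoding is only applied at
file boundaries and inverted on load).

Default study profiles (chosen once as the study conditions; tests and
the acceptance script do not adjust them):

* **Cameras** share a green-dominant sensitivity, diag(0.94, 1.06, 0.98) —
  raw Bayer output leans green before white balance on every phone — and
  differ in near-diagonal crosstalk and, most importantly, in red-channel
  response (×0.94, ×1.04, ×0.90). Between-phone differences in red
  response dominate uncalibrated redness disagreement.
* **Lighting** levels are halogen-like warm casts: high = (1.08, 1.00,
  0.84) at scale 1.0, low = (1.16, 1.00, 0.72) at scale 0.92. The dimmed
  lamp is warmer; the intensity scales are close to each other because
  smartphone auto-exposure largely equalizes mean image brightness, so the
  raw signal difference between 815 lx and 122 lx settings is mostly
  chromatic.
* Vignetting, peripheral hue shift and sensor noise default to **zero**.
  The default run is therefore the idealized case in which calibration can
  be exact; degradations are opt-in keyword arguments and are exercised in
  dedicated tests (e.g. per-camera vignette fields leave reduced-but-
  nonzero post-calibration differences, since a single matrix cannot
  invert a spatially varying field).

All parameter combinations keep the brightest scene/chart pixel below the
0.99 saturation threshold, so no pixels are silently dropped in the
default configuration.

## Chart and calibration

The built-in chart has 18 chromatic patches and a 6-step neutral ramp
(generic values, not the proprietary ColorChecker coordinates; real chart
values can be supplied). The exact mid-gray (0.50) anchors white balance.
Patch measurement averages the interior of each patch, excluding a 20%
border margin and any saturated pixels; a patch more than half saturated
is flagged and excluded from the fit (its fallback mean is still
reported). White balance divides by the neutral patch; the CCM is an
unweighted least-squares fit in linear RGB on patch means (3×3 by
default, 3×4 affine behind a flag — the affine form additionally absorbs
black-level offsets). Applied images are clipped to [0, 1]; no
out-of-gamut reprojection.

Which neutral patch anchors white balance and whether the fit is affine
are deliberately configuration options, not baked-in assumptions.

## Redness metrics

Relative redness is a **sum** of R/(R+G+B) over the ROI (zero-sum pixels
contribute 0), so it scales with the area considered; the red–green and
red–blue differences are N-normalized means; red hue is the fraction of
ROI pixels whose HSL hue is defined (chroma ≥ 0.01, so neutral pixels
never count) and falls in [330°, 360°) ∪ [0°, 30°). The band and floor
are configuration options: the literature does not pin down whether the
red-hue statistic is a pixel fraction, a mean hue or a histogram summary,
and the band-fraction choice was made because it is bounded, scale-free
and testable. The saturation threshold is 0.99 in linear units (≈253/255
in 8 bit). Manual conjunctiva cutting is replaced by mask files;
coordinates are row-major, origin top-left.

Consequences verified by tests: relative redness and red hue are
invariant under uniform intensity scaling (the difference metrics scale
linearly); duplicating the ROI doubles relative redness and leaves the
other three unchanged; all four are non-decreasing in true vessel
coverage through an identity camera.

## Graders

A grader maps true vessel coverage to an Efron-scale grade:
`round_0.1( clamp( 4·coverage + bias + noise, 0, 4 ) )`. Grades depend
only on the scene, never on camera, lighting, magnification or processing
arm — simulated clinicians have *perfect* color constancy, which makes
the null subjective ANOVA a designed property rather than an empirical
finding. The default panel is three noiseless graders with biases −0.10,
0.00, +0.15 (guaranteeing an exactly null subjective table, F = 0 on
every effect). A second panel, `repeatability_graders()`, adds grading
noise with SD 0.11 / 0.22 / 0.27 Efron units per rater — values matching
published per-clinician repeatability for this scale — and drives the
agreement analyses; its within-subject SDs are recovered from replicate
photographs to within sampling error. The Efron scale is taken as 0–4 in
0.1 steps.

## Statistics

* **Within-subject SD**: pooled over subjects,
  `sqrt( Σ_j Σ_k (x_jk − x̄_j)² / Σ_j (k_j − 1) )`.
* **Bland–Altman**: mean(d) ± 1.96·sd(d) with sample SD (n−1); 95% CIs
  for each limit via the standard-error approximation sd·√(3/n) with
  t₀.₉₇₅,ₙ₋₁.
* **RM-ANOVA**: classical univariate decomposition for a balanced
  fully-crossed within-subjects design. Replicates are averaged per
  subject × cell first (replicate is not a design factor). For each
  effect subset E, SS comes from marginal means by inclusion–exclusion;
  the error stratum is the E×subject interaction; F = MS_E/MS_{E×S}. No
  sphericity correction by default (a Greenhouse–Geisser flag exists for
  the single-factor case). Degenerate strata are resolved explicitly:
  if both effect and error SS vanish (relative tolerance 1e-12 of total
  SS), F = 0 and p = 1; if only the error stratum vanishes, F = +inf and
  p = 0. Unbalanced input raises an error naming the missing cells.
* **Bonferroni**: paired t-tests per level pair on per-subject means,
  p multiplied by the number of pairs *within one factor* (the
  conventional reading), capped at 1.
* p-values are stored at full precision; "<0.001" formatting happens only
  in the rendered report.

The decomposition is verified against an explicit nested-sum oracle and
against pingouin on two-factor designs; its type-I error under pure noise
is confirmed at the nominal 5% level (500 simulations per run of the
acceptance script).

## Problem sizes and determinism

Default scenes are 192×192 px (≈22k ROI pixels), chart patches 24 px in
the study (16 px in most tests), and the full default study — 96
acquisitions, 192 scored records, 6 ANOVA tables — runs in a few seconds.
These sizes were chosen so the complete analysis and its verification
batteries execute quickly on one core while leaving the metric and
calibration behavior unchanged from larger renderings. Every generator is
a pure function of (parameters, seed); a master seed fans out to
per-scene, per-acquisition and per-grading sub-seeds, so runs are
bit-reproducible and stages can be regenerated in isolation. Randomized
condition order is recorded in the metadata.

## What the synthetic study shows — and does not

Passing tests demonstrate that *given* a camera whose distortion is a
single linear color transform, the chart-based calibration removes
between-camera and between-lighting differences in the objective metrics
while simulated color-constant graders are unaffected — the qualitative
pattern reported for real smartphone/slit-lamp photography. They do not
validate the metrics against real conjunctival images: real cameras apply
proprietary nonlinear enhancement, real scenes contain specular
highlights, shading and texture the generator omits, real lighting is
inhomogeneous (here opt-in vignetting only), and real graders are noisier
and less factor-blind than the simulated panel. The red-hue metric in
particular responds to color distortions only through pixels near the hue
band edge, which makes its lighting sensitivity intrinsically weak at
n = 4 subjects — visible as marginal lighting p-values in some seeds,
consistent with it being the least lighting-affected metric in human
data.

## Known limitations

* DNG/raw decoding, JPEG arms and vendor processing pipelines are out of
  scope; images enter as linear TIFF/PNG plus masks.
* The forward model's distortions are global-linear plus three specific
  spatial effects (crop, hue rotation, vignette); no chromatic aberration,
  defocus or demosaicing.
* The ANOVA is the classical univariate within-subjects analysis; no
  mixed-effects or multivariate alternatives, no normality checks.
* With 4 subjects the error strata have 3–6 degrees of freedom; borderline
  effects (calibration main effects on some metrics) fluctuate around the
  0.05 threshold across seeds, exactly as expected at this design size.
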
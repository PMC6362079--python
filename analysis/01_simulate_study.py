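#!/usr/bin/env python
"""Generate the synthetic factorial study and inspect its design.

Produces the 4-subject × 24-condition acquisition grid (3 cameras × 2
lighting levels × 2 magnifications × 2 replicates), chart shots for every
(camera, lighting) pair, and the 192-row record metadata table.  Images go
to scratch/ (large, binary); the metadata table to results/.
"""

from pathlib import Path

from redcam.image import save_image, save_mask
from redcam.pipeline import RunConfig
from redcam.scene import generate_study

SEED = 7
ROOT = Path(__file__).resolve().parents[1]

config = RunConfig(seed=SEED)
study = generate_study(
    config.design, config.profiles, config.graders, seed=SEED, chart=config.chart
)

img_dir = ROOT / "scratch" / "images"
img_dir.mkdir(parents=True, exist_ok=True)
for acq in study.acquisitions:
    save_image(img_dir / f"acq{acq.index:03d}.tiff", acq.image)
    save_mask(img_dir / f"acq{acq.index:03d}_mask.png", acq.image.roi_mask)
for key, img in study.chart_images.items():
    save_image(img_dir / f"chart_{key[0]}_{key[1]}.tiff", img)

out = ROOT / "results"
out.mkdir(exist_ok=True)
study.records.to_csv(out / "metadata.csv", index=False)

print(f"subjects and their true vessel coverage:")
for subject, scene in study.scenes.items():
    print(f"  {subject}: {scene.true_redness:.3f}")
print(f"acquisition cells per subject: {config.design.n_acquisition_cells_per_subject}")
print(f"image records (× processing arms): {len(study.records)}")
print(f"wrote {len(study.acquisitions)} acquisitions to {img_dir}")
print(f"wrote metadata to {out / 'metadata.csv'}")
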
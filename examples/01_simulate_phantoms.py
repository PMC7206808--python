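"""Generate a phantom dataset and inspect its ground truth.

The phantom generator produces confocal-like images of the corneal
sub-basal nerve plexus — bright curvilinear fibers that fade in and out of
focus, a radial vignette, cell-like confounders and sensor noise — together
with the exact centerline raster and its analytic length. Because truth is
known exactly, every downstream quantity (CNFL, fractal dimension,
tolerance-Jaccard) can be validated end to end.

Run:  python examples/01_simulate_phantoms.py
"""

import numpy as np

from nervetrace import PhantomConfig, generate_dataset, skeleton_length_mm

# A small multi-subject dataset: each "animal" carries a systematic offset
# in nerve count and brightness, so there is real between-subject variance
# for subject-wise cross-validation to respect.
samples = generate_dataset(n_subjects=5, images_per_subject=3,
                           cfg=PhantomConfig(size_px=192), seed=7)

print(f"{'image':<12} {'subject':<8} {'true CNFL':>10} {'raster CNFL':>12}")
for s in samples:
    raster_cnfl = skeleton_length_mm(s.truth) / s.image.calibration.area_mm2
    print(f"{s.image_id:<12} {s.subject_id:<8} {s.true_cnfl:>10.3f} {raster_cnfl:>12.3f}")

cnfls = [s.true_cnfl for s in samples]
print(f"\nCNFL across the dataset: {min(cnfls):.1f} - {max(cnfls):.1f} mm/mm^2 "
      f"(mean {np.mean(cnfls):.1f})")
print("note: the raster chain-code estimate tracks the analytic digital "
      "length to within ~2%")
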
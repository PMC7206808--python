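"""Flat-fielding and probability-map post-processing, step by step.

Shows the two deterministic ends of the pipeline without any learning:
morphological top-hat background removal on a vignetted phantom, and the
hysteresis -> skeletonize -> de-speckle chain applied to an idealized
probability map built from the phantom's own ground truth.

Run:  python examples/02_preprocess_and_postprocess.py
"""

import numpy as np
from scipy.ndimage import gaussian_filter

from nervetrace import (
    PhantomConfig,
    PostprocessConfig,
    PreprocessConfig,
    ProbabilityMap,
    flatfield,
    generate_phantom,
    postprocess,
    tolerance_jaccard,
)

sample = generate_phantom(PhantomConfig(size_px=192), seed=3)
image = sample.image

# --- flat-fielding -----------------------------------------------------
# The vignette makes the periphery darker than the center; the top-hat
# removes everything wider than the structuring element (disk, 10 px at
# native resolution, rescaled to the image's pixel size).
flat = flatfield(image, PreprocessConfig())
center = image.pixels[80:112, 80:112].mean()
corner = image.pixels[:32, :32].mean()
print(f"raw image:   center {center:6.1f}  corner {corner:6.1f}  "
      f"(ratio {corner / center:.2f})")
center_f = flat.pixels[80:112, 80:112].mean()
corner_f = flat.pixels[:32, :32].mean()
print(f"flat-fielded: center {center_f:6.1f}  corner {corner_f:6.1f}  "
      "(background removed on both)")

# --- post-processing ---------------------------------------------------
# An idealized probability map: the true centerline blurred and rescaled.
# Hysteresis keeps faint mid-sections that connect to confident stretches,
# thinning reduces the tube to 1 px, and fragments under 35 px are dropped.
prob = gaussian_filter(sample.truth.pixels.astype(float), 1.2)
prob = np.clip(prob / prob.max(), 0, 1)
skel = postprocess(ProbabilityMap(prob, image.calibration), PostprocessConfig())

ji = tolerance_jaccard(skel, sample.truth, tol_px=3.0)
print(f"\nrecovered skeleton vs ground truth: tolerance-Jaccard = {ji:.3f}")
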
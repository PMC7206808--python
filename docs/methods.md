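# Methods note

This note records the quantitative conventions used by `nervetrace` and the
reasoning behind the choices that are not forced by the problem statement.

## Calibration and CNFL

Images are square confocal fields, by default 400 µm over 384 px
(pixel size 400/384 ≈ 1.0417 µm, area 0.16 mm²). Corneal nerve fiber
length (CNFL) is the summed centerline length of all traced nerves divided
by the image area, in mm/mm². A useful closed form: a 1-px line spanning
the full image width has 383 axial steps, hence
CNFL = (383 · 400/384)/1000/0.16 ≈ 2.4935 mm/mm².

## Length on a square grid: the digital metric

Skeleton length uses the chain-code estimator: each axial 8-neighbor pair
contributes one pixel size, each diagonal pair √2 pixel sizes, and a
diagonal pair is skipped when one of its common 4-neighbors is foreground
(it is then a shortcut across an axial corner, not a step of the path). An
N-pixel simple path therefore contributes N−1 step lengths.

This estimator measures length in the *digital* (chessboard-with-diagonals)
metric, which exceeds the Euclidean arc length by up to ≈8% for oblique
straight lines — a property of length measurement on a square grid, not a
bug. The phantom generator therefore records its ground truth in the same
metric: per segment, max(|dx|,|dy|) + (√2−1)·min(|dx|,|dy|), evaluated on
~2-px-spaced rounded vertices. With both sides in the same metric, the
chain-code length of the rasterized truth matches the analytic value to
within 2% at native resolution (the residual comes from overlapping
branches and crossings, which the raster union counts once). The Euclidean
arc length is reported alongside (`polyline_length_mm`) for reference.
Rasterization deliberately uses ~2-px-spaced vertices: sub-pixel-spaced
vertices jitter on rounding and add detour pixels, inflating raster length
by up to ~10%.

## Flat-fielding

Background is the grayscale opening of the image with a disk of radius
10 px at native calibration (rescaled proportionally for other pixel
sizes), borders handled by symmetric reflection; the top-hat (image minus
opening) is guaranteed non-negative by anti-extensivity. The disk diameter
comfortably exceeds nerve-fiber width, so fibers survive with their local
contrast while illumination gradients and large cell sheets are removed.

## Segmentation network

Three encoder–decoder architectures share one implementation: channel
width doubles per level from `base_filters`; each level is two 3×3
convolutions (no bias) each followed by batch normalization and ReLU;
2×2 max pooling descends, parameter-free 2× nearest-neighbor upsampling
ascends; the U-Net variants concatenate the same-resolution encoder map
before the decoder convolutions; a final 1×1 convolution (with bias) maps
to two classes. The canonical deep U-Net (depth 4, base 16) has exactly
487,730 trainable parameters: 486,288 convolution weights + 34 final-layer
parameters + 1,408 batch-norm scales and shifts.

The engine is pure NumPy (float32, NHWC) with hand-written backward passes
verified against central finite differences, and Adam. Convolutions are
evaluated as k² shifted matrix multiplications, which is markedly faster
than im2col on CPU at these channel widths. Everything is seeded;
training, inference and all reports are bit-reproducible on CPU.

Training minimizes per-pixel softmax cross-entropy (optionally
foreground-weighted — nerve pixels are a few percent of an image), re-splits
the data 90/10 train/validation at every epoch, augments with random
rotations, shears and flips (image bilinear / mask nearest, both with
reflect padding so border labels stay consistent), and returns the weights
of the best validation epoch. The full-scale schedule is Adam at 1e-3 with
the rate halving every 100 epochs for 650 epochs; the drop rule admits more
than one reading, so a `subtract_floor` mode (subtract 5e-4 every 10
epochs, floored at 1e-5) is exposed as an alternative.

## Post-processing

Hysteresis thresholding at 0.125/0.275 (inclusive, 8-connectivity) keeps
low-probability stretches only when they connect to a high-probability
seed — matching the physics of fibers drifting through the confocal plane.
The mask is thinned to 1-px centerlines (Zhang–Suen-class, via
scikit-image) and skeleton components with strictly fewer than 35 pixels
are discarded.

## Agreement statistics

- **R²** is the squared Pearson correlation; Hinkle's verbal bands label
  the correlation r: ≥0.9 very high, ≥0.7 high, ≥0.5 moderate, else low
  (negative correlations are labelled low regardless of magnitude).
- **ICC** is computed from two-way ANOVA mean squares. The headline variant
  is ICC(2,1) — two-way random effects, absolute agreement, single
  measures — the standard choice for method comparison, where a systematic
  offset between observers should count against agreement;
  the consistency variant ICC(3,1) is available by flag. The implementation
  is tested to 1e-10 against a hand-computed ANOVA oracle and
  cross-checked against `pingouin`, and recovers a known population ICC in
  a simulated two-way random-effects study.
- **Bland–Altman**: mean difference, reproducibility coefficient
  RPC = 1.96 · SD(differences, sample SD), limits of agreement mean ± RPC.
- **Tolerance-Jaccard**: because tracings are one pixel thick, two correct
  centerlines rarely coincide pixel-for-pixel; a pixel counts as matched
  within 3 px (Euclidean, inclusive). The index is symmetric for
  congruent/matched tracings but not in general (TP is counted on the
  automated side, FN on the manual side).

## Phantoms

Nerve centerlines are correlated random walks entering from a random
border (optionally branching), smoothed by cubic-spline resampling.
Rendering: Gaussian-profile tubes (max-combined), sinusoidal along-fiber
fading (floor 0.3), radial vignette (strength 0.6), Gaussian cell blobs,
additive Gaussian noise, and 8-bit quantization. Datasets draw a
per-subject nerve-count center and brightness scale so subject-wise folds
and ICC-style analyses see genuine between-subject variance. Sample seeds
derive from (seed, subject, index), making datasets stable under partial
regeneration. Under the native configuration the true-CNFL distribution
spans the clinically relevant 5–25 mm/mm² range.

## Desk-scale study profile

The full-scale operating point is impractical for routine verification on
one CPU, so `nervetrace.profiles` fixes a reduced profile used by the
acceptance experiment, CLI and examples: 128-px phantoms (confounder
density preserved by scaling cell counts with area), a depth-3/base-8
U-Net without dropout, and 50 epochs at batch size 4, learning rate 2e-3,
foreground weight 4. These sizes are the package's own documented choice:
batch 4 doubles the optimizer steps per epoch (the binding constraint on
a ~25-image training set), dropout is counterproductive at this run
length, and the foreground weight accelerates recall of faint fading
segments. With it, subject-wise 5-fold cross-validation on a 10-subject ×
3-image dataset reaches pooled R² ≥ 0.8 in 7–8 minutes.

## Limitations

- The digital-metric ground truth is the right comparison target for the
  chain-code estimator, but digital lengths are systematically above
  Euclidean arc length (up to ~8% on oblique fibers).
- The NumPy engine is CPU-only and single-threaded-friendly; full-scale
  650-epoch training is supported but slow.
- Phantoms emulate the salient appearance of sub-basal plexus images, not
  their full biological variability; cross-validation results on phantoms
  bound pipeline correctness, not clinical performance.
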
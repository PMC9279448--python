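# Methods

## Quality model

The package treats retinal image quality as a regression problem on a
single continuous scale: the box-counting fractal dimension (FD) of the
segmented vasculature. The underlying assumptions are (i) vessel
segmentation quality degrades monotonically with image quality — blur,
overexposure, uneven illumination and artefacts all erase vessel
contrast before they erase anything else — and (ii) the branching retinal
vasculature is a fractal whose measured complexity drops as vessels
disappear from the segmentation. A dense, fully resolved vasculature
measures FD ≈ 1.6–1.7; a segmentation reduced to a few strokes measures
near 1 (curve-like) or below; an empty segmentation has no defined FD and
is treated as the lowest quality.

Known limitations, inherent to the metric: an image with inadequate field
definition (optic disc outside the frame) can still show crisp macular
vessels and score high, and diseases that genuinely reduce vessel density
(proliferative diabetic retinopathy, pathological myopia) push good
images below the threshold. Deployments that care about these cases need
an optic-disc visibility check or disease-grade-aware thresholds on top.

## Standardization

The FOV mask is recovered by thresholding the grayscale image at a
fraction (default 0.06) of the maximum intensity, closing with a disc of
radius 1% of the smaller image dimension (the frame is edge-padded first
so the closing cannot erode a clipped FOV at the border), and keeping the
largest connected component. The FOV diameter is the larger of the
mask's row and column extents: when the top/bottom circular segments are
clipped by the sensor, the horizontal chord is the uncut diameter. The
crop box is square with side = diameter rounded up to even, centered on
the mask centroid with half-up rounding so an already-centered image
crops to the identity box; out-of-frame regions are black. Color is
resized bilinearly, masks with nearest-neighbor. Coordinates are 0-based
(row, col), boxes half-open. Standardization is idempotent up to
resampling noise (mean absolute channel difference below 2 levels).

## Vessel segmentation

The trainable backend is a symmetric encoder–decoder network: five
encoding blocks (two 3×3 conv + batch-norm + ReLU, then 2×2 max pool)
with output channels 32, 64, 128, 256, 512, five decoding blocks (2×
nearest upsampling, concatenation with the matching encoder skip, two
conv + BN + ReLU) with channels 512, 256, 128, 64, 32, and a 1×1 conv +
sigmoid head. "Same" padding keeps spatial size; the input side must be
divisible by 2⁵. Skip connections are included because the mirrored
channel schedule implies them and they are the field standard for vessel
segmentation. Training minimizes mean pixelwise binary cross entropy
(predictions clipped to [1e-7, 1 − 1e-7]) with Adam at learning rate
2e-4 for 6 epochs by default; augmentation is random rotation (uniform in
±180°, nearest-neighbor for masks so they stay binary) and axis flips.
The implementation is a compact, self-contained NumPy one — im2col
convolutions with hand-written backprop — sized for CPU training at
reduced configurations (side 64, channels 8–128), where two epochs on
eight phantom pairs take seconds; the layer gradients are verified
against finite differences in the test suite.

The weights-free backend is a multiscale Frangi vesselness filter on the
green channel (scales 1, 2, 4, 8 px, dark ridges), masked to an eroded
FOV interior so the rim itself is not detected as a ridge. The raw
response is divided by a fixed scale of 0.1 and clipped to [0, 1]; a
fixed scale rather than per-image max-normalization keeps probabilities
comparable across images, so degraded images produce uniformly weak maps
instead of stretched noise. Probability maps binarize at 0.5 (≥ rule) by
default. On default phantoms this backend recovers the ground-truth tree
with Dice ≈ 0.85–0.90.

## Fractal dimension

`box_counts` overlays a single grid anchored at the top-left corner (no
offset averaging) and counts cells containing at least one foreground
pixel; edge cells may be partial. `estimate_fd` fits log N(ε) against
log(1/ε) by unweighted OLS over all sizes with N > 0 and reports R² as a
fit diagnostic; fewer than two usable points (in particular an empty
mask) yields NaN, which the quality layer maps to the lowest class
rather than raising.

The default box ladder is geometric with ratio √2 from 2 to side/2 —
two rungs per octave across the full scale range. The full range matters:
the near-saturated coarse rungs anchor the fit so that deleting
structure anywhere in the mask strictly lowers the estimate, which is the
property that makes FD a trustworthy quality score (any removed retinal
field, any veiled region, contributes a smaller FD). The cost of the
coarse rungs is a known finite-size bias for area-like compact sets: a
filled disc of radius 400 on a 1024² grid measures ≈ 1.85 rather than 2
because at coarse ε the covering count of a convex set exceeds area/ε²
by a perimeter·ε term. The estimator is exact for sets whose counts
follow the power law across the whole ladder (lines, the Sierpinski
gasket) and recovers the Koch curve within 0.05; for the disc the slope
reaches 2.00 ± 0.05 when measured over rungs well below the diameter
(ε ≤ 64). We keep the full-range default because quality assessment
compares vessel masks with vessel masks, where the whole-range anchor is
what delivers monotonicity.

## Retinal fields

Field geometry is supplied, not detected. Given the optic-disc center
and radius and the macula center, d is the OD-to-macula distance and the
macula field is a disc of radius 0.6·d. The four quadrant fields
(nasal/superior/temporal/inferior) are delimited by the two 45° diagonals
through the macula center, minus the OD and macula discs, clipped to the
FOV; diagonal boundary pixels belong to the horizontal quadrants, and
the nasal quadrant is the one containing the OD (laterality is implied by
the OD position). The six fields partition the FOV exactly, so removing
all of them from any mask inside the FOV leaves nothing (FD NaN).

## Quality thresholds

Binary rule: insufficient iff FD < threshold (NaN insufficient).
Three-class rule: Reject below `reject_below` (default 1.50), Good at or
above `good_at_or_above` (default 1.60), Usable between; boundaries are
inclusive upward for determinism. Thresholds are constrained to the
[0, 1.7] scale and are deployment choices — stricter screening uses a
higher reject threshold.

## Evaluation toolkit

Positive class = sufficient quality; higher FD ⇒ positive; decision rule
score ≥ threshold. Rates follow the standard definitions (TPR = TP/(TP+FN),
FPR = FP/(FP+TN), precision = TP/(TP+FP), recall ≡ TPR); undefined rates
are NaN. ROC and PR curves are computed at all distinct score
thresholds; ROC AUC is the trapezoid area (equal to the Mann–Whitney
pairwise-win probability with ties counted ½), PR AUC integrates the
best-precision envelope over recall. Optimal cutoffs maximize Youden's
J (ROC) or F1 (PR), ties resolved toward the larger threshold. Group
comparisons use Welch's unequal-variance t-test with significance
declared at p < 0.001, and group means carry t-based 95% confidence
intervals.

## Synthetic data

`generate_vessel_tree` grows a recursive binary tree from entry points on
the FOV boundary: roots are evenly spaced in angle (with seeded jitter),
matching how the retinal arcades leave the optic disc in all directions
so every quadrant carries vessels; each branch splits into two children
rotated ±20° (default branch angle 40°) with jitter, lengths taper by
0.78 and stroke widths by 0.80 per level from 8 px (at side 1024), 9
levels deep, 6 roots. The defaults emulate a dense healthy vasculature:
ground-truth trees measure FD ≈ 1.75 on the full-range ladder (slightly
above the nominal 1.7 top of the quality scale — an estimator-scale
effect of the coarse rungs, not extra structure), and the full
vesselness pipeline lands pristine phantoms at FD ≥ 1.6 (Good) across
seeds at both 512² and 1024².

`render_phantom` paints the tree as dark red-brown strokes on an
orange-hued background disc with radial falloff and mild noise, adds a
bright optic disc at 0.55·R right of center (radius 0.085·side), and
keeps the exterior exactly black. Degradations are severity-parameterized
with severity 0 the identity: Gaussian blur (σ = 0.006·side·severity), an
overexposure veil blending toward white and strongest at the periphery
(the "milky-white layer"), a multiplicative left-right illumination
gradient, FOV cropping from the optic-disc side (a field-definition
failure analog), and grey-closing that erases thin vessels. Blur and
overexposure produce strictly decreasing pipeline FDs over severities
{0, 0.5, 1}, and severity-1 overexposure drops phantoms below the reject
threshold.

What the phantoms do not emulate: lesions and pathology, camera vignetting
and chromatic effects, real vessel tortuosity and caliber variation, and
JPEG artefacts. Passing tests therefore demonstrate the internal
consistency and monotone behavior of the pipeline, not clinical
segmentation accuracy on real fundus photographs — that requires a
trained model and annotated data.

## Problem sizes and numerics

The test suite and the acceptance script run phantom studies at side 512
(20 trees for field removal, 50 phantoms for degradation monotonicity)
and training smokes at side 64 with channels 8–128; FD of a fixture
changes by < 0.05 between 512² and 1024² renderings, so the smaller side
is representative. Known-fractal recovery runs at 1024². All generators
and training loops are deterministic given their seeds; box-count
arithmetic is exact integer work, and the only tolerances in the package
are the resampling tolerance of standardization and the OLS fit itself.
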
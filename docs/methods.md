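# Methods

## Problem and pipeline

Deformational plagiocephaly — positional flattening of an infant's skull —
is monitored with a handful of caliper measurements taken on the head
outline seen from above: anteroposterior length, biparietal width,
perimeter, and two transcranial diagonals taken at ±40° from the midline.
Two derived indices summarize the shape: the cranial index
CI = 100·width/length (brachycephaly) and the cranial vault asymmetry
index CVAI = 100·|d_A − d_B|/max(d_A, d_B) (plagiocephaly severity).

This package measures those quantities from a single top-view photograph
in which a 50-Eurocent coin rests on the vertex of the head.  The pipeline
is: standardize the image geometry → segment {background, head, coin} →
calibrate millimetres-per-pixel from the coin → extract a subpixel head
contour → measure the five parameters and the indices → optionally apply a
per-parameter quadratic bias correction.  Two segmentation engines are
provided: a learned fully convolutional network and a classical
Hough-circle/thresholding fallback.

## Synthetic phantoms and the analytic oracle

No public dataset of clinical top-view captures exists, so correctness is
established on synthetic phantoms with analytically known measurements.

A phantom head outline is a smooth periodic radial curve: an ellipse
(nominal length × width) modulated by small even cosine harmonics (cos 2φ,
cos 4φ, relative amplitude ≤ 1.5 %, seeded) and by a localized posterior
flattening that models the plagiocephalic deformation.  The flattening is
a von-Mises-shaped radial dip (κ = 6) centred on the posterior end of one
transcranial diagonal (220° from the anterior direction), with its Fourier
modes k ≤ 2 projected out.  The projection matters: the k = 0..2 content
of a boundary perturbation only resizes, translates, or tilts the shape —
it shifts the area centroid and the principal axis in ways that cancel
most of the intended diagonal asymmetry — whereas the k ≥ 3 residue
changes the diagonals directly.  The filtered dip reads as a posterior
flat spot with a mild contralateral bulge, which is the classic clinical
pattern (occipital flattening with contralateral bossing).  With the peak
dip depth fixed at 15 % of the local radius, the severity parameter
`asymmetry ∈ [0, 1]` maps monotonically onto CVAI ≈ 0–2.6 %, the range
observed in the clinical population the measurement conventions come
from; `asymmetry = 0` gives an exactly mirror-symmetric outline and hence
CVAI = 0.  Head parameters are rejection-sampled so that every phantom's
ground-truth measurements fall inside the clinically recorded caliper
ranges (length 12–17 cm, width 11.3–14.5 cm, circumference 39.2–51 cm,
diagonals 12.1–15.9 / 11.7–16.9 cm, CVAI 0.1–2.6 %).

Rendering places the outline on a canvas (default 96 × 128 px at
0.42–0.52 px/mm — desk scale), rasterizes head and coin masks, and paints
a brownish stocking-cap texture with fabric noise and rim shading, a
bright metallic coin disc (24.25 mm, the official 50-Eurocent diameter),
and a cluttered background of multi-octave value noise plus random
coloured rectangles.  The clutter is deliberately allowed to resemble the
cap so that segmentation cannot be solved by thresholding — mirroring the
real failure mode of head/background confusion.  Rendering is
bit-reproducible per seed.

Ground truth comes from an oracle that evaluates the same measurement
definitions directly on the polygon at full precision, through an
implementation disjoint from the pipeline: principal axis by fan-triangle
covariance diagonalization (pipeline: Green's-theorem line integrals),
chords and perimeter via shapely (pipeline: bespoke edge intersection),
no rasterization anywhere.  The oracle is rigid-motion invariant to
~1e-13 relative.

What the phantoms do *not* emulate: hair, ears and facial features,
perspective and lens distortion, specular highlights, 3-D parallax of the
coin, and real cap wrinkling.  Passing the phantom suite therefore
demonstrates the geometry/measurement chain and the learning machinery,
not clinical-grade segmentation of real photographs.

## Measurement chain

* Contours are extracted with marching squares at the 0.5 iso-level —
  from the label mask, or, on the learned path, from the head+coin
  probability field, which interpolates the boundary between pixel
  centres and is markedly more accurate at coarse resolution.
* Contours are anti-aliased by arc-length resampling (720 points) and
  Fourier truncation to 16 harmonics: stair-step rasterization noise is
  high-frequency, the head shapes are low-order.  Sixteen harmonics keep
  the flattening bump (significant content up to k ≈ 10) while halving
  the noise of a 24-harmonic fit.  An optional robust mode replaces the
  truncation with an iteratively reweighted (Tukey bisquare) harmonic
  regression of the radial profile, down-weighting narrow dents or
  protrusions left by segmentation errors.
* The principal (anteroposterior) axis is the major axis of the second
  central area moments, in (−90°, 90°], with a circle tie-broken to 0°.
  Length and width are caliper extents along/perpendicular to it —
  extents, not chords, so a flattened (concave) posterior cannot shorten
  the nominal length.
* The diagonals are chords through the area centroid at ±40° from the
  axis; CVAI divides by the longer diagonal (configurable: published CVAI
  variants disagree on the denominator).
* Scale calibration uses the equivalent-area diameter of the coin
  component, 2·√(area/π), rather than a circle fit: robust to partial
  occlusion of the rim.  On the learned path the area is the sum of
  coin-class probabilities over the kept component (expected pixel
  coverage), which resolves the ~12 px desk-scale coin to sub-pixel
  precision; calibration error enters every metric output linearly.

Coordinates are row/col with origin at the top-left pixel centre; angles
counterclockwise from the +col axis; contours are explicitly closed
(first vertex = last).

## Standardization and augmentation

A full smartphone frame (2448 × 3264) is downscaled by 3.4 (floor) and
zero-padded symmetrically — odd pixel to bottom/right — to 736 × 960, the
next multiple of 32 as required by a four-level encoder–decoder.
Desk-scale phantoms are rendered at network geometry and pass through
with factor 1.

Training samples are expanded by a declarative augmentation schedule:
horizontal flip (p = 0.5); rotation uniform in ±90° (p = 1.0, bilinear for
images, nearest for masks); additive Gaussian noise, σ ∈ {0.01, 0.05}
(p = 0.2); one of CLAHE (clip 0.04, 8 × 8 tiles), brightness ±0.2, gamma
0.8–1.2, or contrast 0.8–1.2 (p = 0.9); HSV shifts of ±20/±30/±20 8-bit
units (p = 0.9).  Grouping the four photometric operators under a single
one-of draw keeps the schedule coherent where the published table is
ambiguous about their individual likelihoods; the gamma range 0.8–1.2 is
the closest coherent reading of its garbled parameter entry.  Geometric
operations warp image and mask identically; photometric ones never touch
the mask.  The schedule ships as `data/augmentation.yaml`.

## Segmentation network and training

The network is a U-Net-style encoder–decoder: a stem convolution, four
encoder levels of pre-activation residual blocks (GroupNorm → ReLU → 3×3
conv, twice, plus identity or 1×1-projected skip), 2×2 max-pool
downsampling with channel doubling (base 12, capped at 8×), a bottleneck
block, and a decoder that nearest-neighbour-upsamples and concatenates
the matching encoder output before each residual block; a 1×1 convolution
and channel softmax yield the three class probabilities.  At 736 × 960
the bottleneck is 46 × 60; at the desk-scale 96 × 128 it is 6 × 8.

Because the target environment has no deep-learning framework, the
network runs on a compact reverse-mode autodiff engine written on numpy
(im2col convolutions, analytic softmax JVP, Adam), single-threaded,
float32, and bit-reproducible per seed.  An encoder checkpoint trained
elsewhere can be loaded from disk; nothing is downloaded.

The loss is λ·dice + (1−λ)·focal with λ = 0.5.  Dice is class-weighted
(0.2, 1.0, 3.0) for background/head/coin: the published description only
says the coin and head are emphasized, and the coin occupies ~0.8 % of a
desk-scale frame — without the extra weight the coin class is never
predicted in short runs.  Focal uses γ = 2 (γ = 0 recovers cross-entropy);
probabilities are clipped at 1e-7, dice uses ε = 1e-6.  Training is Adam
at 3e-3 with step decay ×0.3 at two milestones, batch 4; the best
validation-F1 (mean of head and coin F1) checkpoint is kept.  Prediction
post-processing keeps only the largest connected component each for head
and coin and flags a coin disjoint from the head bounding box.

Desk-scale reference run (the configuration the tests and the acceptance
script train): 100 phantoms rendered at native geometry (~2 px/mm on a
384 × 512 canvas, 15 % of them on plain dark backgrounds so uncluttered
scenes are in-distribution too), standardized ×4 down to the 96 × 128
network input, split 2:1 by phantom, 30 epochs.  At equal compute, fresh phantoms (new
clutter layouts) generalize better than augmented copies of the same
phantoms, so the reference run spends its budget on phantom count and
leaves `copies = 0`; the augmentation schedule remains available and
tested.  The run takes roughly ten minutes on one CPU and reaches
≥ 0.97 held-out pixel accuracy and ≥ 0.90 head IoU with margin.  Problem
sizes are a deliberate desk-scale stand-in: the published clinical model
was trained on 498 augmented full-resolution images, which neither the
data nor the compute context of this package reproduces.

## Coarse-to-fine measurement

The learned pipeline measures in native image coordinates.  The network
sees only the standardized frame; the predicted soft head contour is
mapped back through the exact standardization transform, then refined
against the native image by a chromaticity-guided step fit
(:func:`morphometry.refine_contour`, two passes: ±8 px then ±3 px): each
boundary normal's intensity profile is split by a two-region variance
criterion, candidates are scored by variance reduction, by how closely
the inner side's chromaticity matches the cap colour estimated from the
segmented head interior (chromaticity is invariant to the rim shading),
and by a Gaussian displacement prior; the per-normal positions enter a
confidence-weighted Tukey-reweighted harmonic regression.  The coin is
re-estimated at native resolution by an Otsu equivalent-area fit seeded
from the mapped-back prediction.  On phantoms this recovers most
parameters to within a few tenths of a percent of the analytic truth —
an order of magnitude below the desk-resolution rasterization floor.

Two variants were evaluated and rejected: snapping boundary points to
gradient-magnitude maxima (chases clutter edges), and adding a bandpass
texture-energy channel with a wider search (destabilizes clean arcs).

## Classical engine

Gaussian blur → local adaptive threshold → morphological opening (the
erosion deletes outlier pixels; the dilation restores boundary position)
→ inner-edge map → circular Hough accumulator over the radius range →
best-vote circle, followed by a subpixel refinement (Otsu split in a
window around the detected centre; centroid and equivalent-area radius
replace the integer-quantized accumulator values).  The head is then the
Otsu-foreground connected component containing the coin centre, after
closing and hole filling; the coin disc is relabelled class 2.  All
structuring-element sizes are documented config defaults — the published
description of this first-generation pipeline omits them.

## Correction models

The bundled quadratic coefficients (per parameter: β₀, β₁, β₂) are the
published regression parameters mapping photographic to caliper values
for height (≡ length), width, perimeter, and left/right diagonals
(≡ diagonals A/B; the published mapping between "left/right" and "A/B" is
not stated, so the identification is configurable).  They encode the bias
of the authors' clinical capture protocol, so the phantom pipeline
defaults to the identity correction; the bundled set is applied with
`--correction default`.  Fitting is ordinary least squares on a centred
Vandermonde design; inputs outside the clinical range ±20 % are flagged
as extrapolation rather than rejected.  In the residual report the
squared-error column is root-mean-squared (cm) so it is unit-consistent
and bounded below by the MAE; the plain mean of squares is available by
flag.

## Evaluation conventions

Confusion matrices are per-pixel, rows = truth.  The scalar sensitivity
and specificity are macro-averaged one-vs-rest values (micro available by
flag); a class absent from the ground truth yields NaN, excluded from the
macro mean, rather than a fake zero.  ROC and precision–recall curves
take thresholds at unique score values with ties grouped; AUC is
trapezoidal; the PR curve stops once full recall is first reached (lower
thresholds only add false positives at the same recall).  ROC AUC equals
the normalized Mann–Whitney U statistic, which the tests verify against
an independent implementation.  IoU/F1 of two empty regions is defined as
1.

## Numerical choices and degenerate inputs

* Chord/edge intersections use a half-open edge convention with a 1e-9
  epsilon overlap and crossing deduplication, so a chord through a vertex
  is counted once; point-in-polygon uses the even-odd rule.
* The oracle's caliper-axis search refines a coarse grid by an iterated
  local parabola fit driven to its fixed point, making it independent of
  where the absolute grid falls (rigid-motion equivariance to machine
  precision).
* A circle has no principal axis: both implementations return 0° by
  convention.
* Dice ε = 1e-6, focal clip 1e-7, GroupNorm ε = 1e-5; He initialization;
  training aborts with a diagnostic on a non-finite loss.
* Coin components under 20 px refuse to calibrate (error) rather than
  return a wild scale.

## Known limitations

* The learned engine is trained and validated on phantoms only; no claim
  is made about real photographs.
* Background clutter whose colour *and* chromaticity both match the cap
  over a wide arc adjacent to the head defeats segmentation and
  refinement alike — the boundary is locally invisible at the network's
  input resolution.  Roughly one phantom in fifteen contains such a
  configuration and can then miss a parameter by several percent; this is
  the same head/background-confusion failure the clinical protocol
  mitigates by prescribing a distinctive cap, and such results should be
  treated as flagged outliers rather than measurements.
* The model does not generalize across large rendering-scale changes
  (e.g. 4× larger coins than trained); the network therefore always runs
  at the standardized geometry, with measurement refined at native
  resolution.
* Perimeter is the 2-D outline arc length of the top view, not the
  clinical circumference measured above the ears on the 3-D head; the
  correction models absorb exactly this kind of systematic offset.
* CVAI precision is boundary-limited: 0.1 percentage points correspond to
  ~0.2 px of localized boundary error at native resolution.  Symmetric
  phantoms typically measure CVAI ≤ 0.05 but occasional scenes reach
  ~0.3.
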
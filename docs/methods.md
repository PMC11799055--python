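# Methods

## The model

The echo envelope `x` of a B-mode frame carries tissue microstructure in
its local amplitude statistics.  In fully developed speckle (many random
scatterers per resolution cell) the envelope is Rayleigh; sparse or
clustered scatterers produce pre-Rayleigh statistics, well described by
the two-parameter Nakagami family with shape `m` (Rayleigh at `m = 1`,
`m < 1` pre-Rayleigh) and spread `Ω = E[X²]`.  Fat droplets deposited in
liver parenchyma change the scatterer population, and with it the shape of
the envelope distribution.

The pipeline quantifies that shape through local moments

    M_n(i, j) = E[ x_k^n ],

the mean of the n-th power of the envelope over an elliptical window
centered on pixel (i, j).  Processing stages:

1. **Iterative normalization.**  The envelope is divided by the square
   root of the local second-order moment, computed over a 4.6 × 10.8 mm
   (depth × lateral) elliptical window — 6 × 8 resolution cells of
   0.76 × 1.35 mm.  This removes focus-, gain- and attenuation-dependent
   brightness.  Pixels brighter than 3 × √M2 are flagged as non-speckle
   (vessel walls, ligaments) and excluded; M2 is recomputed over the
   survivors and the sweep repeats until no pixel is newly excluded.  The
   exclusion set grows monotonically, so the loop always terminates.
   For Rayleigh speckle the expected exclusion fraction is
   P(X > 3√E[X²]) = e⁻⁹ ≈ 1.2 × 10⁻⁴.
2. **Parametric images.**  On the normalized image, first- and
   fourth-order moment maps are formed over a smaller 3.0 × 8.1 mm window
   (4 × 6 resolution cells).  After normalization these are scale-free
   shape descriptors: Rayleigh gives M1 = √π/2 ≈ 0.886 and M4 = 2; for
   Nakagami(m), M1 = Γ(m+½)/(Γ(m)√m) and M4 = (m+1)/m, so M1 rises and
   M4 falls as `m` grows.  Four classifier inputs are rendered: the
   jet-colorized normalized image, the two moment maps, and a moment heat
   map — a 2-D histogram of per-pixel (M1, M4) pairs (M1 horizontal, M4
   vertical, log(1+count) color scale).
3. **ROI extraction.**  20 mm square ROIs (400 px at the standard 50 µm
   pixel spacing) slide on a 4 mm grid; an ROI is kept only if fewer than
   1% of its pixels are unusable (outside the liver mask, excluded as
   non-speckle, or without window support).  Surviving candidates are
   pooled per case and uniformly subsampled to a per-case budget
   (default 256).  All four views of one ROI crop the same pixel window;
   heat-map views are histogrammed from the ROI's own moment values.
4. **Classification and voting.**  A CNN classifies each ROI into G0 / G1
   / G2-3.  Cross-validation is case-grouped and four-fold: per grade the
   cases are split (3, 2, 3, 2); two groups train, one selects the epoch
   with minimum validation loss, one tests, and roles rotate so every ROI
   is tested exactly once.  A case's grade is the majority (hard) vote of
   its ROI predictions; ties break by higher mean class score, then by
   severity.

Grades follow MRI-PDFF thresholds: G0 < 5.2%, 5.2% ≤ G1 < 11.3%,
G2-3 ≥ 11.3% (the moderate/severe boundary at 17.1% is informational;
those grades are merged).  Thresholds are inclusive on the left of the
upper grade, consistent with the reference cohort's 5.0% case being G0.

## Synthetic cohorts

No clinical images ship with the package, so every downstream stage is
exercised on synthetic speckle whose statistics are controlled:

* **iid mode** draws each pixel independently from Nakagami(m, Ω) —
  spatially white, but with exact marginals, so windowed estimators can be
  checked against closed forms.
* **convolved mode** scatters unit-amplitude, random-phase point
  scatterers at a controlled density, convolves with a Gaussian PSF, and
  takes the magnitude.  This gives realistic correlated speckle;
  Gaussian-amplitude scatterers were rejected because their excess
  kurtosis decays too slowly with density (≈ 2.2 at 10 scatterers per PSF
  area versus ≈ 2.08 for unit amplitudes, against the Rayleigh limit 2.0).

Cohorts map grade to a Nakagami shape — default G0: 0.7, G1: 1.0,
G2-3: 1.5 — chosen so normalized M1 rises and M4 falls with grade, the
direction fatty-liver envelope statistics move in vivo.  PDFF is drawn
uniformly within each grade's threshold interval (1.9–5.2 / 5.2–11.3 /
11.3–32.1%, spanning the clinically observed extremes), 10 cases per
grade and 4 images per case by default, with ~0.1% bright non-speckle
pixels injected at 5 × √M2.  Liver masks are irregular convex blobs
covering ≥ 50% of the frame; the pipeline needs only a binary mask, not
anatomy.  Optional CAP/ATI/elasticity columns are affine-plus-noise
stand-ins spanning the clinically reported ranges, for exercising
indicator reports only.

**What this does and does not show.**  Passing tests demonstrate that the
estimators are unbiased, the exclusion rule and geometry behave as
specified, and the learning/voting machinery is sound.  They do not
demonstrate clinical performance: real livers have within-grade
biological variability, depth-dependent attenuation, anatomical texture
and operator variability that the generator deliberately omits, and no
published generative model links PDFF to envelope statistics — the
grade→shape mapping is this package's own stand-in.  Synthetic grades are
far more separable than clinical ones, so end-to-end accuracies on these
cohorts saturate and must not be read as estimates of clinical
performance.

## The classifier

The default backbone is a compact from-scratch CNN on numpy: two 3×3
convolution blocks (8 and 16 channels) with ReLU and 2×2 max pooling, a
32-unit hidden dense layer, softmax output; trained with mini-batch SGD
(batch 64, momentum 0.9, learning rate 0.02, inverted dropout 0.25 before
each dense layer) on 32 × 32 RGB views.  Gradients are clipped to global
L2 norm 1 — without clipping an occasional large mini-batch gradient can
push the small network into a dead all-one-class state.  Backprop is
verified against finite differences in the test suite.

The `vgg16_transfer` backbone name records the original transfer-learning
protocol (VGG-16 with the last fully connected layer replaced by a 3-way
output; only the last two fully connected and last two convolutional
layers trained; batch 64, dropout 0.75, learning rate 7.5 × 10⁻⁵, epoch
selection at minimum validation loss within 18 epochs).  Those protocol
values are the `TrainConfig` defaults, but the mode itself requires
pretrained VGG-16 weights and a deep-learning runtime and raises until
both are provided.

Epoch budget: early stop when validation loss has not improved for 5
epochs, hard cap 18; the returned model carries the best epoch's weights.
Training is deterministic for a fixed seed (data order, weight
initialization and dropout masks are all seeded); bit-identity across
library versions is best-effort.

## Numerical choices

* Window extents are **full axis lengths** (diameters): 4.6/10.8 mm at
  0.76/1.35 mm resolution reproduces the documented 6 × 8 resolution-cell
  description, which a semi-axis reading would not.
* The target pixel participates in its own window's expectation.
* Moment maps run through FFT convolutions of `xⁿ·valid` and of the
  validity indicator; the test suite proves equivalence with the naive
  per-pixel double loop to 1 × 10⁻⁸.
* Exclusion sweeps are synchronous (all over-threshold pixels flagged
  against the same M2 map before recomputation) for order-independence.
* Edge handling: a moment estimate needs at least 25% of its window's
  nominal pixel count; below that the target is invalid.  Invalid and
  excluded pixels render black, count toward the ROI invalid-fraction
  rule, and never enter heat-map counts.  Excluded pixels are flagged, not
  interpolated.
* Heat-map axes are M1 ∈ [0, 1.5] and M4 ∈ [0, 8] (covering Nakagami
  m ∈ [0.5, 5] with margin) with 224 bins by default and log(1+count)
  scaling; out-of-range pairs clip into edge bins so counts are conserved.
  The B-mode display range is [0, 3] in normalized units — the exclusion
  threshold bounds survivors.
* The "at least 4 mm" ROI stride is implemented as exactly 4 mm (the
  densest allowed grid), configurable upward.
* Iterated truncation shifts the moments of what survives: the test-suite
  oracle solves the fixed point t = 3√(M2 of survivors) with incomplete
  gamma functions and checks map means against the truncated expectation
  (for Rayleigh, M4 ≈ 1.99 rather than 2.00).

## Permutation control

The no-signal control permutes the grade-label column of the whole ROI
table once, reruns cross-validation, and scores accuracy against the
permuted labels — the standard permutation-test protocol.  Scoring a
permuted-label model against the *original* labels is not a calibrated
control on synthetic cohorts: within-grade ROIs are statistically
near-identical, so a collapsed model moves whole blocks of them together
and accuracy lands far from 1/3 in either direction even under the null.
Under the label permutation the test labels are exchangeable and
independent of the predictions, so accuracy concentrates binomially
around 1/3.

## Problem sizes

Default generator conditions mirror the clinical acquisition (50 µm
pixels, 10 cases/grade, 4–10 images/case, 20 mm ROIs, 256 ROIs/case).
The packaged end-to-end experiments run a reduced scale chosen for
single-CPU desk use: 200 µm pixels, 60 × 60 mm frames, 4 images/case,
64 ROIs/case, 32 × 32 classifier inputs, 10-epoch budget.  iid speckle is
spatially white, so envelope statistics are invariant to pixel spacing
and the closed-form checks are unaffected by the coarser grid.

## Known limitations

* No scan geometry: images are rectangular grids, not fan-shaped convex
  sweeps; RF simulation, attenuation/TGC and scan conversion are out of
  scope.
* The grade→shape mapping is monotone by construction, so synthetic
  cohorts cannot probe failure modes caused by overlapping grade
  statistics.
* CAP/ATI cut-off values are study-specific and therefore mandatory
  configuration inputs; none are hard-coded.
* Only the count of positive sonographic findings per reference case is
  recoverable in the packaged clinical table; the six individual finding
  flags are stored as unknown.
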
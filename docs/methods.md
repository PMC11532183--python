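# Methods

## Overview

`fibroquant` quantifies liver fibrosis in Sirius-Red (SR)-stained biopsy
sections. The pipeline is: RGB slide → tissue/collagen segmentation in
optical-density space → per-biopsy features at two spatial scales (single
pixel and 32×32-pixel ROI) → stage-wise statistics and inter-rater
agreement → paired pre/post-treatment response calls. The two features with
contractual semantics are the **Estimated Collagen Area** (ECA, the
percentage of tissue pixels that are SR-positive collagen — the digital
analogue of the Collagen Proportionate Area) and the **Entropy of Collagen**
(EnC, the mean local Shannon entropy of the SR optical density, a measure of
textural disorder of the fibrous tissue: low values mean uniform,
homogeneous collagen).

## Segmentation model

Per-channel optical density is `OD = -log10(max(I, 1)/255)`; the `max(·,1)`
caps saturated black pixels at a finite OD (≈2.41 per channel). The scalar
SR optical density of a pixel is the projection of its OD 3-vector onto a
unit SR stain vector. The default stain vectors are fit to the synthetic
palette (collagen RGB (170,30,40), counterstain (235,215,160)); real slides
should supply measured vectors via `SegmentationParams.stain_vectors`. A
single projection (rather than a full stain-matrix inversion) is used
because only the SR channel is consumed downstream; the counterstain vector
is carried for validation of non-collinearity.

Tissue is everything that is not bright, unsaturated background
(HSV value > 220 **and** saturation < 0.08 by default, matching a
near-white scanner background), morphologically closed (disk radius 1) and
cleaned of components smaller than `min_object_px` (default 10 px — small
enough to keep 1-px-wide collagen strands alive in the collagen pass, which
reuses the same parameter). Collagen is the set of tissue pixels whose
SR-projected OD exceeds a threshold; the default is Otsu over tissue-pixel
OD values (parameter-free), with an explicit threshold available for
reproducibility. Raising the threshold can only shrink the collagen mask,
small-object removal included. Segmentation is equivariant under image
flips (all structuring elements are symmetric).

Degenerate inputs: a fully-background image yields an empty tissue mask
with a warning (not an error); an empty tissue mask yields an empty collagen
mask with a warning; a constant-OD tissue region yields no collagen (Otsu
is undefined there).

## EnC operationalization

The published definition of EnC is verbal (randomness of SR OD with respect
to its neighborhood in terms of intensity distribution), so the
operationalization is fully specified here and every choice is a parameter:

- quantize the SR OD into `entropy_bins` = 8 equal-width bins spanning the
  slide's tissue OD range (per-slide normalization makes EnC insensitive to
  global stain intensity);
- at each pixel, form the histogram of the quantized OD over the tissue
  pixels inside a centered `entropy_window_px` = 9 square window
  (windows truncate at image borders; counting only tissue pixels means
  background never dilutes border entropies, and a constant-over-tissue OD
  field scores exactly 0 everywhere);
- the pixel's local entropy is the Shannon entropy of that histogram in
  natural log (configurable to log2);
- EnC is the mean local entropy over tissue pixels (configurable to collagen
  pixels).

With these defaults EnC is bounded by ln 8 ≈ 2.08, consistent with the
0.6–2.1 range such entropies take on real biopsies. The window counts are
computed exactly with integer integral images, so the implementation agrees
with a naive O(N·w²) sliding-window oracle to better than 1e-9.

## ROI features and the extended battery

The slide is tiled into non-overlapping 32×32-px ROIs (partial edge tiles
included, their tissue fraction taken over the actual tile area); ROIs with
tissue fraction below 50% are flagged excluded (biopsy fragments have ragged
borders; configurable). Per ROI the battery computes: collagen fraction;
OD mean/sd/skewness/kurtosis; local-entropy mean; co-occurrence contrast,
energy, homogeneity and correlation on the 8-level quantized OD (offsets
(0,1) and (1,0) pooled, symmetric, counting only pixel pairs where both
pixels are tissue — the reason the co-occurrence accumulator is written
in-package rather than taken from `skimage.feature.graycomatrix`, which has
no mask support); collagen component count, perimeter density and
anisotropy (eigenvalue elongation of the collagen pixel cloud,
`(λ1−λ2)/(λ1+λ2)`).

Slide-level extended features are tissue-weighted means and sds of the
per-ROI values over included ROIs, giving a named, versioned registry of
28 features (`FEATURE_REGISTRY`); only ECA and EnC carry contractual
semantics, the rest are a documented configurable battery. The
tissue-weighted mean of per-ROI collagen fractions over *all* ROIs equals
ECA/100 exactly (tiling conservation).

Numerical conventions: skewness/kurtosis of a constant ROI are defined as
0; co-occurrence correlation of a zero-variance ROI is defined as 1
(matching skimage); ROI statistics use population (ddof=0) variance.

## Synthetic slide generator

The generator emulates what the segmentation and features need from an SR
slide — a near-white background (RGB ≈ 245), a pale-yellow parenchymal
counterstain (≈ (235,215,160)) and saturated-red collagen (≈ (170,30,40)),
colors chosen to be separable in OD space like real SR stains — with exact
ground-truth masks. The tissue section is a smoothed random blob (largest
component, hole-filled, ~60% of the frame). Collagen is laid down as portal
tract disks plus random-walk polylines: at low `disorder` mostly thick
(7-px) compact septa bridging portal-tract centers; at high `disorder`
mostly thin (1-px) short scattered strands with larger angular noise.
Strokes are added until the target pixel count is reached and the final
stroke's tail is trimmed, so the achieved collagen fraction matches
`target_collagen_fraction` to within one tissue pixel. Optional additive
Gaussian RGB noise. All randomness derives from one integer seed;
identical specs yield bit-identical slides.

Default study conditions: 0.25 µm/pixel (a 40× scan), collagen fractions
around the F2/F3/F4 stage means 2.6%/5.7%/10.9% for cohort generation,
disorder 0.3, no noise. What the generator does **not** emulate:
steatosis, ballooning, inflammation, stain batch variation, scanner
artifacts, anti-aliased edges, or perisinusoidal fine texture. Passing the
ground-truth recovery tests therefore shows the pipeline's machinery is
correct (exact counting, thresholding, entropy), not that its defaults are
tuned for any particular scanner's real slides — real-slide use requires
user-supplied stain vectors and threshold checks.

## Statistics

- **Fleiss κ** over the six fine CRN stages (F1a,F1b,F1c,F2,F3,F4) by
  default, with a coarse option collapsing F1a/b/c → F1; the computation
  delegates to `statsmodels.stats.inter_rater.fleiss_kappa` and is
  cross-checked against a direct formula implementation in the tests.
  Perfect agreement returns exactly 1.0 even when chance agreement Pe = 1
  (all ratings one category), where the formula is otherwise undefined.
- **Agreement bands**: κ is rounded to 2 decimals, then matched against the
  inclusive Landis–Koch ranges (0.01–0.20 slight, 0.21–0.40 fair,
  0.41–0.60 moderate, 0.61–0.80 substantial, above that almost perfect;
  ≤ 0 "poor/none"). Rounding first makes the banding total; the boundary
  value 0.81 is assigned to "almost perfect".
- **Paired t-test**: two-sided `scipy.stats.ttest_rel`, significance at
  p < 0.05; zero-variance differences raise rather than returning a
  meaningless statistic.
- **ANOVA + Tukey**: `scipy.stats.f_oneway` plus `scipy.stats.tukey_hsd`
  (studentized-range adjusted pairwise p), with significance stars at
  0.05/0.01/0.001/0.0001. With two groups the Tukey p equals the pooled
  two-sample t-test p.
- **Stage summaries** report n, mean, sd, SEM, IQR, min, max. Both sd and
  SEM are always reported because error-bar conventions vary; IQR uses
  linear-interpolation quartiles (the convention must be stated — it is not
  universal).

## Response classification

Stages are totally ordered F1a < F1b < F1c < F2 < F3 < F4 (coarse F1 for
agreement analyses). The histology call is the sign of the ordinal stage
delta. The AI call is *responder* iff ECA **and** EnC both strictly
decreased, *non-responder* iff both strictly increased, *not conclusive*
otherwise; an exactly-zero delta in either feature breaks congruity (a
strict reading; no packaged case has a zero delta at recorded precision).
Feature values are compared at their recorded precision with no
re-rounding. Swapping pre and post maps responder ↔ non-responder and
stage-decrease ↔ stage-increase. Cohort percentages use half-up integer
rounding (e.g. 9/17 → 53%, 4/17 → 24%). Two "AI change" notions are
reported separately: *any* change (both deltas nonzero) and *congruous*
change (responder or non-responder).

The clinical weight-loss outcome is strict: more than 10% weight loss
between biopsies, i.e. `weight_change_percent < −10`; −10 exactly is
negative, missing values propagate as None.

The packaged cohort tables transcribe the study (9 pairs) and validation
(8 pairs) cohorts. Their `weight_change_pct` column is a synthetic
stand-in: per-patient weight changes were not published, only that exactly
study patients 2 and 6 crossed the −10% threshold and no validation patient
did; the fixture satisfies those constraints with invented magnitudes and
says so in its header.

## Problem sizes and limitations

Validation runs use 256–512-px synthetic slides (20 slides for the ECA
counting check, 5 seeds per disorder level for the entropy-gradient check,
a 128×128 crop for the brute-force entropy oracle) and a 10-slide
1024×1024 cohort for the end-to-end determinism check; these sizes exercise
every code path while keeping the full suite fast. Known limitations:
no pyramidal/tiled WSI streaming (slides must fit in memory); no stain
normalization across scanners; the extended battery stands in for a feature
list that was never published, so only ECA and EnC should be compared
across implementations; cohort-level feature distributions of the original
biopsies cannot be reproduced without the original slides and are not
attempted.
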
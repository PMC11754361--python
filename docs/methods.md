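# Methods

This note documents the models, conventions and numerical choices behind
`fgsquant`, and what the synthetic phantoms do and do not establish about
real specimen imaging.

## Signal ratio model

The IR image is treated as an 8-bit raster in arbitrary intensity units
(0–255). MFI statistics over an ROI are the mean, minimum, maximum and
*population* standard deviation of exactly the rasterized ROI pixels; a
pixel belongs to a polygon ROI iff its center lies inside the ring.
Ratios are ratios of ROI means (not means of per-pixel ratios), so they are
invariant under any common linear rescaling of the image before clipping.
Adequacy classes follow the established intraoperative cutoffs with the
boundary convention: exactly 3 → sufficient, exactly 1.5 → suboptimal.
RGB IR exports are collapsed to one channel; when the three channels are
identical (the common case for grayscale exports in RGB containers) that
channel is used unchanged, otherwise a Rec.-709 luma average rounded
half-up. Linearity of the camera export is assumed.

The tumor volume helper uses the ellipsoid approximation
V = π/6 · d₁d₂d₃ from three orthogonal diameters.

## Phantom generator

`make_phantom` emulates a specimen imaged on a black table: an elliptical or
blobby tumor footprint, margin bands at two distances obtained from the
Euclidean distance transform of the footprint (band widths configurable, 10
px defaults), a disjoint tumor-bed patch, and an IR image whose expectation
is `background_mfi` everywhere except `background_mfi · true_tbr` inside the
tumor. Noise is additive Gaussian, clipped to [0, 255] and rounded half-up
to 8 bits — the simplest model consistent with 8-bit imaging; a flag records
when the configured contrast exceeds the 8-bit range. Optional
inflammation-like false-positive foci are bright disks in the outer margin
band. With `noise_sd = 0` the measured tumor-to-background ratio equals
`true_tbr` exactly whenever `background_mfi` and the product are integral
(8-bit rounding is the only discretization); the calibration checks use such
configurations. The default study conditions are a 192² px image,
background 40, contrast 3, noise SD 2 — a clearly "sufficient" contrast
with realistic shot-to-shot variation.

All randomness flows from one integer seed per call (`numpy` PCG64);
identical configuration and seed give bit-identical rasters.

What the phantoms do *not* model: dye pharmacokinetics, camera optics,
working-distance and angulation effects, tissue texture and
autofluorescence structure, or 3-D tissue. Passing tests therefore
establish correctness of the measurement chain, not instrument-level
performance on real specimens.

## Section deformation and registration

Mounted histologic sections acquire a similarity offset (rotation, slight
scale change, shift, occasionally a flip) plus smooth local distortion.
`make_section_pair` applies a known similarity about the image center
followed by a sum-of-Gaussians displacement field (default bandwidth 30 px,
amplitude 4 px at the mounting-artefact preset; amplitudes above the
bandwidth are rejected as fold-prone). Masks are warped by inverse mapping
with nearest-neighbour sampling; the nonrigid part is inverted by
fixed-point iteration, accurate to well under 0.1 px at these amplitudes.

Registration resamples both tissue outlines to n = 256 arc-length-uniform
points and searches all n cyclic correspondences × 2 traversal directions,
fitting a closed-form least-squares similarity per candidate (orthogonal
Procrustes; reflection allowed by default since sections can be mounted
flipped). The discrete search quantizes rotation at 360/n degrees for
near-circular outlines, so a golden-section refinement over the fractional
correspondence offset follows. Outlines are extracted from a lightly
Gaussian-smoothed mask (σ = 1 px) before marching squares: the staircase
boundary of a binary raster has orientation-dependent arc length, which
would otherwise bias the correspondence by 1–2°. With these choices,
similarity parameters of rigid deformations are recovered to ≲ 0.3°,
≲ 0.2 % scale and ≲ 0.3 px on the default phantoms — comfortably inside the
1° / 1 % / 1 px targets.

Residual boundary mismatch is absorbed by Gaussian-kernel ridge regression
of the matched-point residuals (bandwidth = the `smoothness` parameter,
default 15 px; fixed relative ridge 10⁻²). Because the ridge only shrinks
the fitted displacement, the boundary residual RMSD never exceeds the
similarity-only residual, and it grows monotonically as `smoothness`
forces broader corrections. Whole-tissue Dice after registration flags a
"successful" matching at ≥ 0.80 — deliberately below the ~0.90 mean quality
of successful matchings so only clear failures are flagged.

## Detection calls and accuracy

A section's NIRF call operationalizes visual reading: pixels above
background mean + k·SD (default k = 3) form the positive mask, specks below
25 px are discarded, and a section is positive when at least that minimum
area of its tissue fluoresces. Sensitivity, specificity, accuracy,
correct-call shares and the false-positive rate are reported as percentages
rounded half-up to one decimal with exact Clopper–Pearson CIs (the CI
method is recorded in the output; sections are treated as independent).
The reference cohort preset (76 TP / 56 TN / 16 FP / 0 FN) reports the
published false-positive rate under both printed denominators — 16/148 =
10.8 % and 16/149 = 10.7 % — and flags the discrepancy instead of resolving
it.

## IHC quantification

Stain segmentation uses hematoxylin–eosin–DAB color deconvolution
(`skimage.color.rgb2hed`) and thresholds the DAB optical density (default
0.15). Stained area is normalized to the 10-high-power-field reference of
2.37 mm² (stained_area = stained_fraction · 2.37×10⁶ µm²), so it is linear
in the stained fraction by construction. Mean staining intensity is kept on
the raw pixel scale where darker (stronger) staining gives *lower* values;
this is why stained area correlates positively and mean intensity
negatively with the fluorescence ratio on a cohort where target expression
drives both. Expression positivity uses the > 10 % stained-fraction rule;
the low/intermediate/high category bins (10 / 25 / 50 %) are explicitly
configuration placeholders, not a validated grading rubric, and are
recorded in the output. Default scale 0.5 µm/px (typical 20× scan).

The IHC phantom places exactly ⌊fraction·n⌋ stained pixels uniformly in
each ROI and colors them through the inverse deconvolution at a chosen
optical density, so fraction recovery is exact up to segmentation error;
real slides add nuclear texture, stain gradients and edge effects the
phantom does not attempt.

## Statistical layer

Two-sided tests throughout, p < 0.05 convention. Mann–Whitney uses the
exact null for the smaller group ≤ 8 without ties, otherwise the
tie-corrected normal approximation. Kruskal–Wallis reports the
tie-corrected H against the χ² reference and, for total n ≤ 10, an exact
permutation p alongside. Dunn's post hoc z uses the pooled-rank variance
with tie correction; the multiplicity adjustment defaults to Holm
(Bonferroni available) and is recorded in the result. Spearman p is exact
by enumeration for n ≤ 7, t-approximate otherwise. Boxplot summaries follow
the min-max whisker convention with type-7 (linear interpolation)
quartiles. A Monte-Carlo harness estimates Kruskal–Wallis power at a given
location-shift design.

## Problem sizes and reproducibility

The shipped analyses use 192² px phantoms, 20 sections for registration
quality, 100 random deformations for similarity recovery, a 148-section
detection cohort, 50 IHC phantoms for fraction recovery and a 19-case
coupled cohort for the correlation signs — sizes at which every stochastic
summary in the test suite is stable across seeds while the whole suite and
the acceptance script each run in well under a minute of compute. Every
entry point takes an explicit seed; reports embed the configuration hash.

## Known limitations

* The registration is outline-based only; sections whose distortion moves
  interior structure without changing the outline are corrected only as far
  as the boundary constrains the field.
* Near-symmetric outlines (ellipse-like tissue) make rotation recovery
  ambiguous up to the symmetry; the generators use blobby, asymmetric
  footprints for recovery experiments, and real sections are likewise
  asymmetric.
* The NIRF positivity threshold is an explicit, configurable stand-in for a
  human reader; no claim is made that k = 3 SDs matches any particular
  reader's operating point.
* Stain segmentation assumes DAB-like stain vectors; other chromogens need
  their own deconvolution matrix.
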
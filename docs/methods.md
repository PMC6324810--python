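# Methods

This note documents the models, estimators and numerical choices behind
`angioarch`: what each stage computes, which parameters matter, what the
synthetic data do and do not emulate, and the known limitations.

## Substrate geometry

Seven architectures are modelled with their measured post-sintering
dimensions (the slurry shrinks during sintering, so the as-designed
radii — 400/200 µm — are kept only as metadata):

| design        | width (µm) | periodicity (µm) | depth/height (µm) | polarity |
|---------------|-----------:|-----------------:|------------------:|----------|
| large         | 660        | 1240             | 300               | concave  |
| large_deep    | 660        | 1240             | 585               | concave  |
| large_convex  | 660        | 1240             | 300               | convex   |
| small         | 330        | 630              | 150               | concave  |
| small_deep    | 330        | 630              | 300               | concave  |
| small_convex  | 330        | 630              | 150               | convex   |
| flat          | —          | —                | 0                 | flat     |

Depth `z` is measured downward from the ridge plane, so grooves are
`z > 0`. The cross-section of a feature of width `w` and depth `D` is a
circular arc of radius `r = w/2`: a semicircle under vertical walls of
height `D − r` when `D > r` (the "deep" variants), and the arc scaled to
the measured depth (a semi-ellipse) when `D ≤ r` (e.g. the large
concavity, 300 µm deep with a 330 µm radius). Convex designs are the
mirror image, bumps rising from a base plane at `z = D`. With phase 0
each feature is centred in its period; groove intervals are half-open
`[start, end)` in µm and partial intervals clipped at the frame boundary
are kept, since real samples are cropped mid-pattern. For convex designs
"grooves" are the regions between bumps.

## Synthetic co-culture stacks

The study's raw images are not deposited, so the generator emulates the
features of them that the analysis actually consumes:

- **Microcapillary-like structures.** Smooth random curves (length
  uniform between 500 µm and min(3000 µm, 0.9 × frame)), rendered with a
  Gaussian cross-profile (FWHM `filament_width_um`, default 20 µm) at
  unit peak amplitude. Orientations are axial von Mises draws centred on
  the groove axis with concentration `alignment_kappa`; κ = 0 is exactly
  uniform. Unconfined structures are tortuous (smooth heading wander,
  sd 25° at κ = 0, shrinking as 25°/(1 + κ/4) — guidance that
  concentrates orientations also straightens structures) and sprout
  Poisson(1.5) lateral branches at 25–65° offsets. Structures placed
  inside a groove (probability `containment_prob`) are unbranched and
  nearly straight: wall confinement, the study's own qualitative
  observation. Containment is enforced exactly — a confined structure is
  resampled until its full x-extent fits inside one groove interval.
- **The co-culture monolayer.** A continuous faint sheet (amplitude
  0.015 of the filament peak, smooth ±30% texture) draped over the
  substrate surface, plus sparse brighter cell-sized spots (150 /mm²,
  12 µm FWHM, amplitude 0.4). CD31 is endothelial-specific, so
  non-vessel cells are dim; but the sheet is what lets a depth profile
  be measured over ridges as well as grooves, exactly as the confluent
  day-7 monolayer does in the real stacks. Spots are individually below
  the 400 µm² particle cutoff and the sheet is too dim to survive
  Phansalkar thresholding, so neither contaminates the segmentation.
- **Z structure.** Ten slices span [0, depth + 50 µm]. All surface
  signal sits at the substrate depth at its x position with a one-slice
  Gaussian bleed, so depth maps are recoverable.
- **Background and noise.** A smooth low-amplitude gradient (3% of
  peak) models autofluorescence/illumination. Noise is signal-dependent
  (shot-like): σ(v) = (1/snr)·sqrt(0.005 + v), so `snr` (default 8) is
  the peak-filament signal-to-noise and dark background is
  proportionally cleaner — the regime in which local adaptive
  thresholding of real confocal data operates. (Spatially uniform
  Gaussian noise is not a viable model here: auto-contrast normalizes
  the noise scale, after which Phansalkar marks ~half of any Gaussian
  field as foreground and percolating clusters defeat the particle
  filter even on empty images.)

Identical arguments and seed give bit-identical stacks. What passing
tests on these data do **not** show: robustness to real-world tile
seams, uneven staining, out-of-focus haze, anastomosing network
topology, or vessels that leave the substrate surface.

## Preprocessing

Fixed order, as two paths with a common head: max-intensity projection →
rotation to put grooves at 0° and centred crop (2400 × 2100 px =
5740 × 5023 µm at 2.3917 µm/px; the crop must contain no out-of-bounds
fill) → rolling-ball background subtraction (radius 50 px). The
directionality path stops there; the localization path continues with
auto-contrast (0.7% total saturation, the common display-autoscale
convention), 8-bit conversion, Phansalkar thresholding and particle
removal below 400 µm² (= 69.93 px; components of exactly 400 µm² are
kept, 8-connectivity so diagonal vessel fragments do not fragment).

- **Rolling ball.** Morphological background estimation with a ball
  structuring element. By default the estimate is computed on a
  block-minimum-reduced image with proportionally reduced radius and
  bilinearly upsampled — the shrink schedule (1/2/4/8 by radius) of the
  ImageJ implementation the study ran, which is 200× faster at radius 50
  than the exact construction (`downscale=1`, also available). The
  upsampled background is clamped below the image, so output ≤ input
  holds exactly.
- **Phansalkar.** With intensities normalized to [0, 1] and local mean
  µ and sd σ over a disk of radius 5 px (square window optional,
  mirror-padded borders): `t = µ·(1 + p·e^{−qµ} + k·(σ/r − 1))`,
  foreground iff `I > t`. The constants k = 0.25, r = 0.5, p = 2, q = 10
  are the parameterization the method is universally distributed with;
  all are config-exposed. The implementation is validated against a
  literal per-pixel oracle.

## Orientation analysis and DOA

The orientation histogram (90 bins of 2° over [−90°, 90°), 0° = groove
axis, counterclockwise positive) is built from the Hann-apodized power
spectrum. Three estimator choices matter for sparse structures on a
cartesian grid:

1. **Physical-frequency annulus.** Orientations and radii use physical
   frequencies (cycles/µm), so a non-square frame carries no angular
   distortion. The inner radius is max(3 cycles/image, n_bins/π grid
   cycles): below n_bins/π the grid cannot populate every bin per shell
   and the exact-axis grid lines hoard low-frequency power in precisely
   the 0° and 90° bins that DOA uses (measured: 2.3× axis-bin excess
   with a 3-cycle cutoff). The outer radius, 0.08 cycles/µm (12.5 µm
   period) by default, caps the band at the sub-cellular texture scale;
   it widens automatically if a small frame cannot resolve it.
2. **Per-bin mean, not sum** — cancels the anisotropic grid density of
   rectangular frames.
3. **Radial whitening.** Each of 40 log-spaced shells is normalized to
   its mean power, so no single scale (in particular the few giant
   low-frequency coherence cells of a 40-structure image) dominates the
   angular distribution. On isotropic synthetic images this brings the
   single-bin DOA ratio to 1.05 ± 0.24 per image (heavy-tailed ~1.3
   without it); on strongly aligned synthetic samples DOA reaches 3–7,
   the study's reported range.

DOA averages bins within a window (full width `window_deg`, default 2° =
one bin) around 0° and around ±90° (wrapped) and returns their ratio.
Zero perpendicular signal returns an infinite-alignment sentinel, never
a silent division. DOA is scale-invariant by construction.

## Groove detection and DOC

`depth_profile_from_stack` measures the surface depth along three
300-µm-wide horizontal bands (centre of the crop ± one band; per-x
median combines them). Within a band, intensities are pooled laterally
over ~15 µm; the diffuse background — near-uniform across Z, unlike
surface-bound signal — is removed as the per-column minimum over slices;
depth is the intensity-weighted centroid of the slices within ±2 of the
brightest (immune to the uniform-in-Z noise floor; plain arg-max
optional). Columns below 1% of the median column total are interpolated
from neighbours; more than 50% missing is an error. On synthetic stacks
this recovers groove-centre depths within 0.6 × z-spacing and profile
RMS errors of 5–20 µm.

`detect_grooves` maps the six published parameters onto an explicit
pipeline (the original plugin's internals are unpublished, so this *is*
the specification, validated against analytic ground truth rather than
the plugin's bitwise output):

1. smooth depth with a moving mean of span `curvature ×
   rolling_z_window` (40 µm at defaults);
2. relative depth against the ridge plane, taken as the global minimum
   of the smoothed depth — a 100 µm *rolling* baseline cannot work
   here, since every feature (330/660 µm) is wider than the window and
   a local baseline would track the groove floor itself;
3. candidate points deeper than `z_threshold` × depth range;
4. each candidate-run edge moves to the strongest slope point exceeding
   `slope_factor × max|dz/dx|` within `rolling_z_window` of it. Concave
   walls, convex bump bases and boundary-clipped features all present
   their slope maximum at the true edge, so this direction-agnostic
   rule recovers all three cases (an outward-only scan fails for convex
   designs, where the true edge lies inward of the half-depth point);
5. intervals scored `normalized depth + depth_weighting × normalized
   curvature`, discarded below `depth_weighting`;
6. intervals closer than `rolling_z_window / 2` merged.

A profile with depth range below 1% of the rolling window is flat — an
empty groove set, not an error. On noiseless analytic profiles of all
six designs over 5740 µm, detected counts equal ground truth, centres
land within 12 µm and widths within 15%; on measured synthetic stacks,
counts still match with centres within ~10 µm.

DOC divides the mean mask signal per µm inside grooves by that outside.
Lengths are counted as profile samples × sample spacing, so a constant
profile gives DOC = 1 exactly at any sampling. All signal inside grooves
gives an infinite-containment sentinel; no grooves (flat design — the
pipeline skips detection there) gives an undefined, flagged result.
Whether "signal" is the binary mask (default) or grayscale intensity is
config-selectable.

## Group statistics

Per-architecture mean and SEM (sd/√n; undefined for n = 1), then a
Kruskal-Wallis omnibus test with tie correction and Dunn's pairwise
z-tests on mean ranks, flagged at the 0.05 and 0.005 cutoffs. Dunn
p-values are unadjusted by default (Holm optional). With n = 3 per group
the chi-square approximation is badly conservative (measured type-I
≈ 0.01 at α = 0.05), so for small totals (≤ 50 000 partitions) the
omnibus p-value is the exact permutation tail of H — the standard
small-sample treatment, giving the nominal 5% rate. Non-finite sentinel
DOA/DOC values are excluded from testing with a warning and a count.

## Problem sizes and determinism

Analyses default to the study's full 2400 × 2100 px frame; the test and
reference runs use the half-scale preset (1200 × 1050 px, same
2.3917 µm/px pixel pitch) and a 600 × 526 px frame for the orientation
sweeps — the statistics of both scale cleanly because all thresholds are
physical (µm, µm²). The reference script averages 10 isotropic images;
monotonicity checks use 10 seeds per condition. Every source of
randomness flows from a single integer seed; identical config + seed
reproduces every CSV byte-for-byte, and each run writes a manifest
(config echo, package version, input checksum).

## Known limitations

- The groove-detection parameter semantics are this package's mapping of
  the published six numbers; equivalence with the original plugin's
  internals cannot be established from public material.
- The orientation estimator's band cap (0.08 cycles/µm) assumes
  structures at least ~12 µm wide; much thinner fibres would need a
  wider band.
- Depth profiling requires some fluorescent signal across the whole
  cross-section (in practice: a confluent monolayer); sparse cultures on
  bare substrate leave ridges unmeasured.
- DOC compares signal *density* in/out of grooves; it does not correct
  for the larger surface area of a grooved region versus its projected
  length.
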
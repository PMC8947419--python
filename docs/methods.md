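# Methods

## Problem and approach

Melon fly (*Zeugodacus cucurbitae*) control by the sterile insect technique
requires sorting males from females before release, ideally at the pupal
stage. Male pupae carry long pectinate setae (comb bristles) on the backplane
of the penultimate abdominal segment; these become visible through the pupal
case about two days before eclosion. Females carry only the shorter setae
that occur in both sexes. `pupavision` implements the image-analysis chain
that turns a day-series of single-pupa microscope photographs into a
male/female call, and evaluates the calls against eclosion outcomes.

The chain, per frame:

1. **Range normalization.** Raw 3-channel TIFFs span [0, 65520]; they are
   mapped onto [0, 255] by `p -> round_half_up(p * 255 / 65520)`. Round half
   up is used everywhere a rounding rule is needed; endpoints map exactly.
2. **HSV conversion.** The pupal case is strongly colored and the background
   nearly neutral, so the saturation channel `S = (max - min) / max` gives
   the cleanest foreground contrast. S is kept on a [0, 255] integer scale
   so that thresholding operates on an 8-bit histogram. Hue (0-360 deg mapped
   onto [0, 255]) is computed for completeness but unused.
3. **Segmentation.** Otsu's threshold on the 256-bin S histogram (ties broken
   toward the smaller threshold; foreground is the bright, high-S side),
   hole filling (background components not connected to the border),
   morphological opening with a disk of radius 5 px (raw scale), and the
   largest 8-connected component. A failed segmentation quarantines the
   frame; the pupa is excluded from that day only.
4. **Pose normalization.** The minimum-area enclosing ellipse of the mask is
   computed with Khachiyan's minimum-volume-enclosing-ellipsoid algorithm on
   the convex hull of the boundary pixels (the result is inflated by the
   worst-case violation so every hull point is contained exactly). The
   rectangle circumscribing the ellipse (sides 2a x 2b at the ellipse angle)
   supplies the rotation; the frame is rotated (bilinear, zero padding) so
   the body axis is horizontal, cropped to the rectangle (floor/ceil integer
   bounds) and resized to exactly 2800 x 1300. The resize is anisotropic by
   construction; a per-axis calibration `um_per_px * crop_extent/std_extent`
   is carried so physical lengths survive the distortion.
5. **Grid features.** The standard frame is tiled into 5 x 5 = 25 cells of
   560 x 260 px (row-major, 1-based, top-left origin). Per cell: mean gray,
   gray standard deviation, dark fraction (pixels below `mean - 2*std`,
   floored at 0), and gray-level co-occurrence contrast (offset 1 px
   horizontal, 32 quantization levels). The temporal screen computes, per
   feature, the cohort-mean absolute change of each cell on day *d* versus
   day 1, z-scores the (cell, day) table, and ranks cells by the maximum over
   days and features. On tail-left-oriented pupae the male signal
   concentrates in cell 17 (row 4, column 2).
6. **Setae detection and call.** In the tail cell, dark pixels are those
   below `mean - 2*std` of the cell. Because that threshold sits just below
   the cell mean, each stripe carries a wide interpolation skirt that can
   chain neighbors into one component; every component is therefore reduced
   to its half-depth core (pixels at or below halfway between the cell mean
   and the component's darkest level) and the core blobs are re-labeled and
   measured individually. Blobs are filtered by area (>= 20 px), elongation
   (principal-axis ratio >= 3) and orientation (within 30 deg of
   perpendicular to the body axis). Length is the extent of the core pixel
   centers projected on the principal axis, converted to mm through the
   per-axis calibration projected onto the stripe direction. A day is called
   male when at least one stripe is strictly longer than 0.05 mm; a pupa is
   male if any day is (latch rule; no day gating, matching the retrospective
   screening design).
7. **Evaluation.** Calls are cross-tabulated against eclosion outcomes
   (female / male / unfledged). Unfledged pupae are excluded from all
   accuracy denominators: group accuracies are males-among-positives over
   positives-that-eclosed and females-among-negatives over
   negatives-that-eclosed; overall accuracy is their joint ratio over all
   eclosed pupae. Percentages are reported to one decimal, rounding half up.
   On the published 500-pupa counts (124 setae-positive, all male; 376
   negative: 310 female / 18 male / 48 unfledged) this yields 100.0%, 94.5%
   and 96.0%; the overall denominator 452 = 500 - 48 is the only arithmetic
   consistent with the published 96.0% and 94.5% figures.

## Decision parameters

| parameter | default | meaning |
| --- | --- | --- |
| `long_threshold_mm` | 0.05 | stripes strictly longer are "long" (male-only). The published length ranges overlap exactly at 0.05 mm; the boundary itself is assigned to "short". |
| `min_long_count` | 1 | long stripes needed for a male call. Recognition rests on setae presence; the 16-20 anatomical count is a generator parameter and diagnostic, not a decision rule. |
| `elongation_min` | 3 | principal-axis ratio below which a dark blob is not a stripe. |
| `orientation_band_deg` | 30 | allowed deviation from perpendicular-to-body-axis. |
| `dark_k` | 2 | multiplier on the cell standard deviation for the dark threshold. |
| `min_area_px` | 20 | speckle guard on core blobs, standardized pixels. |
| `opening_radius` | 5 px | disk radius of the segmentation opening, raw scale. |

## Synthetic cohort: what it emulates, and what it does not

No images are distributed with the study this package models, so the
generator produces the cohort the pipeline is tested on. It emulates the
acquisition design: one pupa per frame, one 3-channel wide-range TIFF per day
for 11 days, eclosion on day 12 for pupae that emerge.

* **Body.** A saturated ellipse (RGB ~ (0.80, 0.50, 0.20), S = 0.75) on a
  near-neutral background (S = 0.10), so that Otsu separation on S is
  well-posed — the premise of the segmentation design. Semi-axes are drawn
  per pupa at 1.80-2.00 mm by 0.72-0.82 mm (a ~4 mm pupa), the center
  jitters +-15 px, and the body sits at a per-pupa rotation drawn from
  (-35, 35) deg with +-2 deg day-to-day repositioning jitter. Keeping
  rotations well inside (-90, 90) makes pose normalization flip-free, so the
  canonical tail-left rendering always lands the setae band in grid cell 17;
  the mirrored cell (19) is exposed for data with the opposite convention.
* **Setae.** Rendered as anti-aliased capsules (line segments with round
  caps; the recorded length is tip-to-tip), oriented within +-20 deg of
  perpendicular to the body axis, arranged as an evenly spaced comb along a
  common row on the ventral side of the tail — overlapping setae would fuse
  into blobs no detector could separate, and the comb anatomy spaces them in
  reality too. Long setae: 16-20 per male, lengths uniform in 0.05-0.18 mm,
  darker (multiplicative depth 0.50-0.60); rendered only on males and only on
  the two days before eclosion. Short setae: 6-10 per pupa, 0.02-0.05 mm,
  lighter (0.25-0.35), rendered on both sexes in the same window. Unfledged
  pupae never develop setae. Multiplicative darkening leaves saturation
  invariant, so setae do not perturb segmentation.
* **Scale and noise.** Default calibration 5 um/px (a 0.05 mm seta is 10 raw
  px); frames are 1000 x 800 px. Additive Gaussian noise with sd 600 raw
  gray levels (~2.3 8-bit levels), clipped to [0, 65520].
* **Cohort assignment.** `round_half_up(n * male_fraction)` males;
  independently `round_half_up(n * unfledged_fraction)` unfledged, chosen
  uniformly regardless of sex. All randomness derives from the config seed
  (per-pupa and per-day substreams), so equal seeds give bit-identical
  cohorts.

Not emulated: real pupal-case texture and its temporal drift, illumination
gradients, the optical clearing produced by the day-8 water immersion
(carried only as a metadata flag), debris and focus errors, and the
biological variability that produced the published 18 setae-negative males
(dysplasia; in the generator every eclosing male expresses setae). Passing
the synthetic recovery study therefore demonstrates that the chain is
correct and calibrated — that a comb of >0.05 mm transverse dark stripes two
days before eclosion is found, measured physically, and attributed to the
right cohort members — not that the published real-image accuracy would be
reproduced on new photographs.

## Numerical choices and degenerate inputs

* Rounding is half-up wherever a rule is needed (range normalization, S
  quantization, reported percentages, cohort counts); the sources are silent
  on ties.
* Otsu ties break toward the smallest threshold; constant images raise.
* Stripe length uses the *half-depth core* extent of pixel centers. This
  FWHM-style measure ignores the anti-aliased tips and interpolation skirt,
  reading about one raw pixel short: deliberately conservative so that
  interpolation blur never promotes a boundary short seta (<= 0.05 mm) over
  the male decision threshold. The residual bias (~ -0.002 mm at default
  scale) is far inside the 10% accuracy the detector is tested to.
* Khachiyan MVEE: relative duality-gap tolerance 1e-3, max 2000 iterations,
  then exact containment enforced by inflating to the worst hull-point
  violation (< 0.3% in practice). Masks with < 5 boundary points or collinear
  hulls raise a degenerate-geometry error.
* The 2800 x 1300 resize is applied even when it distorts aspect ratio (both
  dimensions are part of the standard-frame contract); length measurements
  rely on the propagated per-axis calibration instead of assuming isotropy.
* Rectangles are half-open with 0-based top-left origin; rotation
  interpolation is bilinear with zero padding.
* Empty cohorts, all-unfledged cohorts (accuracies reported as NA with a
  warning) and per-frame segmentation failures (quarantined, logged,
  excluded from that day) are handled without aborting a run.

## Open design points

* Head/tail orientation is not identifiable from a single silhouette. The
  package adopts tail-left as the canonical post-straightening orientation
  (this matches grid cell 17 being the discriminative cell); the mirrored
  tail cell 19 can be checked via `check_mirror_cell` / `mirror_index` when
  the convention of the data is unknown.
* The enclosing rectangle is the one circumscribing the fitted ellipse (same
  center and angle, sides 2a x 2b) rather than a minimum-area rectangle of
  the raw mask; the ellipse-based construction is what makes the angle
  estimate robust to boundary noise.
* The texture feature set (mean, std, dark fraction, co-occurrence contrast)
  is fixed and documented so the screening result is reproducible; the
  screening conclusion only requires some feature sensitive to added dark
  stripes.
* The source study's text mentions a nine-pupa setae-positive figure in one
  passage while its contingency table counts 124 setae-positive pupae (the
  nine appear to be the detections made as early as day 10 in a
  sub-experiment). The evaluation module follows the contingency table
  (124); the inconsistency is noted here rather than resolved.

## Problem sizes used in the shipped checks

The synthetic recovery study runs 100 pupae x 11 days (50 male, 10%
unfledged, default noise) — 1100 frames end to end. Unit and property tests
use 4-8 pupae with 1-4 day series; the determinism check runs a 4-pupa,
3-day cohort through the on-disk pipeline twice and compares bytes.
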
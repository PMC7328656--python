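# Methods

## Problem setting

A digitized herbarium sheet is an RGB image of a pressed specimen.
Four reproductive-structure categories are scored per sheet: flower
buds, flowers, immature fruits and mature fruits (in Brassicaceae such
as *Streptanthus*, the fruits are long thin siliques). Two derived
metacategories, `buds_flowers` and `fruits`, are never stored — they
are recomputed from the four primary categories wherever reported.
The package evaluates how well an instance-segmentation model detects,
classifies, counts and measures these organs, and constructs the three
annotation regimes such models are trained on.

## Coordinate and mask conventions

Pixels are 0-based, origin top-left, x rightward, y downward. Bounding
boxes `(x, y, w, h)` are half-open, so `w`·`h` is a pixel count. A
pixel belongs to a polygon mask iff its center `(j+0.5, i+0.5)` lies
strictly inside the polygon; centers exactly on a polygon edge are
excluded, a deterministic tie-break that can matter only for
zero-measure vertex configurations. Masks are stored as polygons in
annotation files and rasterized lazily over their local bounding
window. Raster-only masks (point and partial masks) are serialized by
tracing a marching-squares contour halfway between foreground and
background pixel centers; under the center-containment rule this
round-trips the raster exactly for simply connected components. The
conversion keeps the filled outer boundary of the largest connected
component — interior holes are not preserved, which is acceptable for
organ masks (solid shapes).

Sheets are resized so the *longest* edge is 2048 px with aspect ratio
preserved. Fixed 2048×1024 output is only consistent for 2:1 sheets;
non-uniform scaling would corrupt downstream size measurement, so
aspect preservation is the deliberate choice and the short edge is
whatever the aspect ratio dictates.

## Annotation regimes

* **Point masks.** A 3×3-px square centered on each marker, clipped at
  image borders (2×2 at a corner, 2×3 on an edge).
* **Partial masks.** In a 100×100-px window centered on the marker
  (even window size spans `[c−50, c+50)`, left/top biased; clipped at
  borders), the luminance channel (0.299 R + 0.587 G + 0.114 B) is
  thresholded with Otsu's method, implemented from first principles:
  the threshold t maximizes the between-class variance
  ω₀ω₁(μ₀−μ₁)² over all 256 candidate levels, with class 0 = {levels
  ≤ t} and ties broken toward the smallest t. The foreground is the
  class containing the marker pixel (with ≤-semantics a marker sitting
  exactly at the threshold falls in the darker class — appropriate
  since plant material is darker than mounting paper). Of the
  foreground's 8-connected components the one containing the marker is
  kept; if none contains it, the one with the nearest centroid. A
  single-level (degenerate) window falls back to the point mask with a
  logged warning.
* **Full masks.** Hand-drawn outlines; `validate_full_masks` reports
  self-intersecting polygons, zero rasterized area and duplicate
  geometry. When organs overlap, only the foreground structure is
  annotated; the reader makes no attempt at de-occlusion.

## Matching and metrics

Matching is greedy in decreasing prediction score (ties: input order);
each prediction claims the unclaimed ground-truth instance of highest
IoU, kept only if IoU strictly exceeds the threshold (default 0.5).
Claims are **category-agnostic**: if matching required label agreement,
a flower detected as a bud would register as a miss plus a false alarm
and the confusion matrix could never observe cross-category confusion.
Label correctness is instead judged where it belongs:

* **AP** ranks predictions of a category by decreasing score and sums
  precision-at-k over the ranks whose matched ground-truth instance has
  the same category, divided by that category's ground-truth count.
  Unmatched predictions of the category occupy ranks (lowering later
  precisions) but contribute no correct hit.
* **Size-wise AP** pools all categories and partitions ground truth by
  max bounding-box side into Small (1–64 px), Medium (65–128 px) and
  Large (> 128 px). Matched predictions are binned by their matched
  instance's size, unmatched ones by their own. Note the two distinct
  size notions: *binning* uses the max bbox side (0.54 / 1.08 cm at
  default calibration), *measurement* uses the bbox diagonal (the same
  64- and 128-px squares read 0.76 / 1.52 cm as diagonals). Reported
  cm values are rounded to 2 decimals.
* **Counting precision** needs no matching: it is 100 × (predictions
  with score ≥ the counting threshold, default 0.5) / (true count),
  per sheet and category. The ratio direction is chosen so that values
  above 100% mean overcounting, matching how the metric is read.
  Measurement precision uses the same direction
  (100 × mean predicted size / mean true size). Both are undefined
  (reported as missing, not zero) when the reference set is empty.
* **Confusion matrix** row i, column j: fraction of ground-truth
  instances of category i matched by a prediction of category j; with
  one-to-one matching each instance has at most one (its best-scoring)
  match. The row deficit from 1 is the misdetection probability.

## Synthetic data

The generator emulates the *geometry and scale regime* of annotated
sheets, not their appearance: buds are ellipses (10–40 px, elongation
≤ 2), flowers lobed discs (30–90 px), immature fruits thin curved
capsules (length 60–250 px, width 6–14 px), mature fruits broader
capsules (120–360 × 8–18 px); per-category colors separate the classes
in hue the way green/purple/brown organs do. Default per-sheet counts
(13, 17, 9, 10) follow the category proportions of the reference
training set (279, 349, 196, 212 over 21 sheets) scaled to ~50 organs;
the fixture generator reproduces those totals exactly, plus the test
composition (168, 299, 110, 101 over 10 sheets), allocating instances
to sheets by a seeded multinomial. Organs are placed by rejection
sampling with disjoint, gap-padded bounding boxes (default gap 8 px),
so ground-truth masks never overlap; requesting more area than the
sheet can hold raises an infeasible-packing error. All randomness
derives from one integer seed through `SeedSequence` spawning, making
images and annotations byte-reproducible.

What passing tests on this generator do **not** show: robustness to
overlapping and deteriorated organs, stems, glue, labels and
handwriting, photometric variation between herbaria, or real organ
morphology — the qualities that make real sheets hard. The synthetic
suite validates the *metrics and plumbing*, not any detector's
real-world performance.

The perturbation model corrupts ground truth with independent
per-category miss probabilities, Poisson false alarms, a row-stochastic
label-swap matrix and mask jitter, yielding closed-form expectations
(pooled CP → 100·(1−p); confusion(i,j) → (1−pᵢ)·Sᵢⱼ) that the test
suite verifies within 3-sigma binomial bounds. Two deliberate choices:

* **Scores.** Detections draw scores from a beta variate mapped into
  [0.55, 1] and false alarms into [0.5, 0.7), so every surviving
  prediction clears the default counting threshold of 0.5 — this keeps
  the analytic CP expectation exact rather than dependent on a beta
  tail probability — while detections still outrank false alarms in
  expectation, as a trained model's softmax scores would.
* **Jitter** is dilation-only (disk of the given radius, plus optional
  boundary-pixel noise). Erosion can annihilate thin silique masks,
  and pure dilation guarantees per-instance IoU decreases monotonically
  with radius. Jitter-monotonicity checks match at a low IoU threshold
  (0.1) so the matched population stays fixed across radii and the
  comparison isolates geometry from match churn.

## Baseline detector

The reference `Segmenter` is classical: Otsu split on luminance
(foreground = the darker side), 8-connected components, then a rule
table on per-component area, elongation (major/minor axis ratio) and
mean HSV hue — elongation ≥ 3 → fruit, hue separating immature (green)
from mature (brown); compact components split flower (purple) from bud
(green, small). Scores map the rule margin into [0.5, 1]. Thresholds
live in `BaselineConfig`, tuned once on the synthetic suite and frozen;
on that suite the baseline holds per-category recall ≥ 0.8 at
IoU > 50% — an engineering floor for pipeline tests, not a claim about
real specimens. Neural detectors are out of scope by design; their COCO
results files plug in through `CocoResultsSegmenter`.

## Numerical choices and problem sizes

IoU is computed by pixel counting on the union bounding window of the
two rasters; a zero-area mask is a hard error. Otsu ties break to the
smallest threshold; matching ties break to input order (predictions)
and lower index (ground truth). The test suite and acceptance script
use annotation-only generation (no rendering) wherever images are not
needed, with suites of 3–11 default sheets (~150–540 instances) for
end-to-end and recovery checks, 100+ random windows/suites for oracle
equivalence, and a 4-point jitter grid — sizes chosen to keep binomial
3-sigma bounds tight while the whole suite runs in well under a minute
per module on one CPU.

## Known limitations

* Polygon serialization does not support RLE or holes; multi-component
  rasters serialize as their largest component's outer boundary.
* The confusion matrix conditions on geometric matching at the same
  IoU threshold as AP; organs detected with grossly wrong extent count
  as misdetections, not confusions.
* CP counts predictions above a score threshold (default 0.5); a model
  whose calibrated scores concentrate below it will look like an
  undercounter. The threshold is configurable everywhere it appears.
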
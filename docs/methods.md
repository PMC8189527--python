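# Methods

## The object-gaze distance

A mobile eye tracker yields (i) a fixation table — each fixation a time span
and one gaze coordinate in scene-camera pixels — and (ii) per-frame binary
segmentation masks for each area of interest (AOI), typically produced by an
instance-segmentation network.  The object-gaze distance (OGD) of a fixation
with respect to an AOI is the minimal Euclidean distance, in pixels, from the
gaze coordinate to the AOI's mask.  Conventions:

* **Coordinates.** 0-based pixel indices, origin top-left, x rightward,
  y downward.  Pixel (row i, col j) has its center at the continuous point
  (x = j, y = i).  Gaze coordinates are continuous floats and are never
  clamped to the frame.
* **Distance target.** Distances are measured to mask pixel *centers*, i.e.
  to the rasterized mask as a point set, not to a vectorized contour.  This
  keeps an exhaustive minimum over true pixels an exact, independent oracle
  for the fast implementation (a k-d tree over the true-pixel coordinates).
* **AOI Hit.** A fixation whose gaze rounds into a true pixel (round half
  up per axis) has OGD = 0 — containment, exactly the classical Hit test.
* **Multiple instances.** If an AOI is detected as several instances in one
  frame, the minimum across instances is taken.
* **Sentinel.** If the AOI has no mask in the selected frame(s), the record
  takes the frame-diagonal value of the configured camera (1600 px at
  1280×960) and carries a sentinel flag.  The diagonal also caps every
  distance, so the series lives on [0, diagonal].
* **Frame selection.** A fixation spans many video frames; the distance is
  computed on the frame nearest its temporal midpoint
  (`round((start + duration/2) · fps)`, the `midpoint` policy) by default.
  The `all_frames` policy evaluates every overlapped frame and combines the
  per-frame values (median by default; min and mean available).  Frames in
  which the AOI is absent contribute the diagonal cap to the aggregate; the
  record is flagged sentinel only when the AOI is absent in *all* selected
  frames.

## Camera geometry and vision bands

The px/° scale of the scene camera is `width_px / hfov_deg`, the horizontal
axis being the reference (one isotropic threshold set, not per-axis scales;
this reproduces the published 640 px near-peripheral threshold exactly at
1280 px / 60°).  Fields of vision are given as angular *diameters* — foveal
2°, parafoveal 9°, perifoveal 18°, near-peripheral 60° — while OGD
thresholds are radii around the gaze point, so the conversion is
`(diameter/2) · px_per_deg`.  Two threshold modes exist: `table_defaults`
returns the published rounded values (20/90/180/640 px; only valid for the
reference 1280×960/60° geometry, and note these roundings follow no single
rule — exact conversion gives 21.3/96/192/640), and `derived_from_camera`
converts exactly for any camera.  Band classification is half-open,
[lo, hi), so a Hit (0 px) is foveal, every distance belongs to exactly one
band, and ≥ 640 px is `outside`; sentinel records classify as `undetected`
regardless of value.

## Derived metrics

The fixation rate of an AOI at threshold d is the fraction of all fixations
with OGD ≤ d.  The comparison is inclusive so that FR(0) equals the
classical Hit rate, and sentinel records count in the denominator (they
satisfy only the diagonal cap, hence FR(diagonal) = 1).  The FR curve
evaluates the grid {0, 10, 20, …, diagonal} by default.  Across trials the
default is per-trial curves averaged with equal weight (`pooled`
concatenates denominators instead).  A dwell-time-weighted FR is available
behind a `durations_s` argument but off by default: the metric counts
fixations.  Mask quality is summarized by IoU, intersection area over union
area of predicted vs reference masks; the IoU of two empty masks is defined
as 0 and logged, since neither area exists.

## Gaze patterns

On the joint series of two AOIs, four qualitative shapes are made
operational by explicit rules (all thresholds are parameters of
`PatternParams`; defaults in brackets):

1. **Glance** — a run of Hits on one AOI while the other AOI's distance
   rises by more than `tolerance_px` [5 px], followed within
   `return_window` [3] fixations by a return to within
   `return_tolerance_px` [30 px] of the pre-Hit distance.  A Hit that never
   ends is a sustained fixation, not a glance.
2. **Convergence** — both distances non-increasing (allowing `tolerance_px`
   of counter-movement per step) over at least `min_len` [2] steps, ending
   with both below the foveal threshold and a Hit on exactly one AOI.
3. **Joint excursion** — both distances cross the perifoveal threshold
   upward on the same fixation and both return below it before the series
   ends.
4. **Disappearance** — one distance rises to or beyond the near-peripheral
   threshold (equivalently, the AOI becomes undetected and is sentinel-
   capped) while the other stays inside the perifoveal field throughout.

The detectors run on fixation-indexed series.  Glance is directional and is
evaluated in both orientations of a pair; the other three handle both role
assignments internally.  Events of different types may overlap and are all
reported; within one detector and one pair, events never overlap.  These
rules are this package's own operational definitions of shapes that are
described only qualitatively in the literature; the published occurrence
counts stem from recordings that are not available, so the detectors are
validated on constructed fixtures (below), not against those counts.

## Synthetic scenes and error bounds

The generator builds trials of 1–3 rigid objects — disks and axis-aligned
rectangles with per-frame trajectories — rasterized into per-frame masks,
with seeded per-label detection dropout emulating segmentation misses, and a
fixation track with uniform random gaze points.  Defaults mirror the
recording conditions the method targets: a 60°-hfov scene camera, two
closely handled tool-like objects, ~0.1–0.2 dropout.  The default fixation
track starts one fixation per frame period and fills 80 % of it, the
remainder standing in for the saccade; this also keeps each fixation's
temporal midpoint safely inside one frame, so frame selection is not
sensitive to float round-off after a CSV round trip.  All randomness derives
from a single seed with purpose-split streams (dropout, gaze noise, track),
so changing one setting never perturbs another and reruns are bit-identical.

Every fixation × object pair has a closed-form ground-truth distance
(disk: `max(0, ‖g−c‖ − r)`; rectangle: distance to the box, 0 inside),
evaluated at the midpoint frame.  Rasterization includes a pixel when its
center lies within half a pixel of the continuous shape (√2/2 px radially
for disks, 0.5 px per axis for rectangles).  Under that convention, for any
record that is not Hit-clamped the pipeline distance D and analytic distance
d obey |D − d| ≤ √2/2:

* lower bound — every included center is within the shape dilated by √2/2,
  so D ≥ d − √2/2;
* upper bound — the analytic nearest boundary point b lies at dilated
  radius minus √2/2, its containing cell's center p is within √2/2 of b and
  hence included, so D ≤ d + √2/2.

A plain center-in rasterization does not have this property: its one-sided
error reaches √2 px when the shape boundary passes just beyond a row of
pixel centers (observed 1.05 px on integer-aligned disks).  The one
remaining exception is the Hit clamp: pixel containment quantizes the gaze
to its cell (diameter √2), so an OGD of exactly 0 can occur with the gaze up
to √2 px outside the continuous shape.  No inclusion radius removes this —
shrinking the mask to protect the Hit test re-opens the distance-side gap
(the min-max over inclusion radii is 3√2/4) — so the recovery tests assert
the two-branch bound: |D − d| ≤ √2/2 for D > 0, and d ≤ √2 for Hit-clamped
records.  Dropout frames must be *exactly* the sentinel.

What the generator does not emulate: real segmentation masks have ragged,
biased contours rather than ideal shapes; eye-tracker noise is neither
isotropic nor Gaussian (a Gaussian gaze-noise option exists for robustness
experiments only); objects can overlap in depth, which a label-image
encoding cannot represent (the writer warns and assigns shared pixels to the
higher label).  Passing the synthetic suites therefore validates the
geometry, bookkeeping and detectors — not the quality of any upstream
segmentation on real video.

## Numerical and interface choices

* Gaze rounding is floor(g + 0.5) per axis (round half up), applied
  identically in the fast path and the brute-force oracle; the oracle shares
  no distance code with the implementation.
* The fast distance and the exhaustive minimum agree exactly for integer
  gaze coordinates (both reduce to the square root of the same exact integer)
  and to 1e-9 px otherwise.
* COCO-style polygon rasterization includes a pixel when its center, nudged
  by a half-pixel toward the lower-right with an epsilon tie-break, lies
  inside the polygon — an axis-aligned w×h box covers exactly w·h pixels,
  half-open on the max edges.  Uncompressed (integer-counts, column-major)
  RLE is supported; compressed string-counts RLE is rejected by name.
* Readers fail loudly: missing columns and unknown label values are errors
  naming the offender; unsorted fixation tables are sorted with a warning;
  temporally overlapping fixations are a hard error.
* The CLI writes a manifest (command, package version, config echo, no
  timestamps) next to every output, and uses exit codes 0 (success),
  2 (configuration error), 3 (data validation error), 1 (unexpected).

## Problem sizes

The synthetic validation scenes use a 320×240 px camera with the reference
60° optics — the px/° scale and all band geometry scale linearly, while
masks stay cheap to rasterize — with 510 fixations × 2 AOIs (1 020 records)
for the recovery suite, 200 random mask/gaze cases for oracle equivalence,
and 24 embedded instances per pattern type for detector validation.

## Known limitations

* The OGD is a 2D image-plane distance; parallax between gaze depth and
  object depth is not corrected, and no lens-distortion model is applied.
* One isotropic px/° scale (horizontal) is used; cameras with strongly
  anisotropic optics would need per-axis thresholds.
* Pattern counts depend on the operational thresholds above; they are tools
  for finding candidate events, not calibrated estimators of the published
  occurrence statistics.
* Published rounded thresholds (20/90/180/640) are available only for the
  reference camera; other cameras always use exact conversion.
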
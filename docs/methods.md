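# Methods

This note documents the models, conventions and numerical choices behind
the three quantification pipelines and their statistics, and what the
synthetic-data generators do and do not emulate.

## Image model and conventions

All images are 2-D float arrays with intensities in [0, 1], rescaled from
the source file by the maximum representable value of its bit depth (255
or 65535), never by the observed maximum — so a fixed threshold means the
same physical brightness across images. Coordinates are row-major,
0-based (row, col), origin top-left. Pixel calibration (`pixel_size_mm`)
is a mandatory user input with no default: it depends entirely on the
acquisition optics. Foreground objects use 8-neighbor connectivity and
background 4-neighbor (the standard duality; anything else lets a
diagonal "wall" both connect and leak).

Otsu's threshold is computed on a 256-bin histogram over the fixed [0, 1]
range by exhaustively scoring every bin boundary with the between-class
variance w0·w1·(mu0 − mu1)²; ties resolve to the lowest boundary. The
default of 256 bins matches 8-bit acquisition. The returned value is the
upper edge of the best lower class, so `pixels > threshold` selects the
bright class.

Watershed dissection seeds from local maxima of the interior Euclidean
distance transform, with maxima closer than `min_seed_distance` (default
5 px) suppressed and plateau maxima merged into one seed, so an isolated
convex object yields exactly one basin while touching objects split at
the distance-ridge between them. The result is always a partition of the
input mask.

## Aggregate-size quantification

Plate scans show cell aggregates darker than the agar. The pipeline:

1. **Background correction** — `clamp(background − scene, 0, 1)` against
   an averaged cell-free image; this simultaneously flattens the
   inhomogeneous field and inverts the scale so clumps become bright on a
   near-zero background.
2. **Segmentation** — one global threshold, set manually per experiment
   and shared by every image (automatic threshold selection is
   deliberately out of scope); watershed applied uniformly to split
   touching aggregates; objects below `min_object_area_px` (default 5)
   removed as dust. The dust filter replaces manual curation with an
   objective rule; it also means aggregates smaller than the filter are
   unmeasurable, which bounds the smallest usable size class at a given
   calibration.
3. **Measurement** — per-object area in mm² (pixel count × pixel size²),
   binned into four half-open size classes I: < b1, II: [b1, b2),
   III: [b2, b3), IV: ≥ b3. The default bounds (0.001, 0.01, 0.1) mm² are
   logarithmic decades placing millimetre-scale aggregates in class IV;
   they are a declared convention and fully configurable.
4. **Statistic** — per class, the total covered area (mm²) normalized per
   cm² of imaged field, plus across-replicate mean and sample SD.

The pipeline is threshold-monotone (raising the threshold never increases
total labelled area) because watershed partitions whatever the threshold
admits.

## Biofilm genotype segregation

Two channels (RFP/GFP) of one colony are fused by pixelwise mean, and the
colony is found by iterative Otsu expansion: the first pass thresholds
the whole image; each later pass re-thresholds only the pixels outside
the current mask and accretes newly-bright pixels 8-connected to it, so a
colony whose margin is dimmer than its core is still captured in full.
Three stop rules: (a) the outside split must actually separate two
intensity classes — Otsu's eta (between-class variance over total
variance) at the candidate split must exceed 0.75. Unimodal Gaussian
noise yields eta ≈ 0.64, so without this guard a pass over pure
background noise bisects the noise and the candidates percolate into the
mask; genuinely bimodal outside regions (a dim colony margin against
background) score near 1. (b) added area below `stop_fraction` (default
0.005) of the current mask; (c) `max_iter` (default 10). The final mask
is hole-filled and reduced to its largest component.

Channels are normalized by subtracting the median intensity outside the
colony (medium autofluorescence) and dividing by the 99th percentile
inside (fluorophore-magnitude equalization); both statistics are robust
to the minority genotype and to hot pixels. Outputs are clipped to [0, 1].

The segregation readout is the fraction of pixels whose normalized RFP
strictly exceeds their normalized GFP — ties count against RFP — measured
along a ring 50 px inside the colony edge (pixels whose
distance-to-background lies within half a pixel of depth+1; depth 0 is
the boundary contour) and over the whole colony. The pixel-count
definition is the operational one; an intensity-sum mode is available
behind a flag. The superior strain's edge fraction over the inferior's
gives the dominance ratio, capped at 1000 when the inferior fraction is
0, and binned into five half-open categories with default bounds
(1.5, 4, 20, 100) — a declared convention, configurable.

## Force-curve analytics

A force-distance cycle is two segments of (separation µm, force nN)
samples. F_max is the depth of the retraction minimum below the
free-cantilever baseline, reported as a positive magnitude. The baseline
(offset + linear drift in separation) is estimated by least squares on
the final 40% of the retract segment — the fully separated regime — and
subtracted from both segments. The tail fraction matters: the fit must
be extrapolated back to the adhesion well, and the extrapolation variance
grows with the squared distance between the well and the tail centroid.
With a 20% tail the extrapolation error dominates the F_max error budget
(measured ≈ 0.17 nN SD at 0.1 nN sample noise, versus ≈ 0.06 nN at 40%),
so 40% is the default; it remains entirely inside the separated regime
for curves whose rupture completes within the first 60% of the retract,
and is configurable (capped at 50%) for curves with late ruptures.

Curves are ingested from a vendor-neutral delimited format (`# key=value`
headers, then `separation_um, force_nN, segment` rows); vendor binary
formats are out of scope and left to a user-side converter. Group
summaries use the sample SD (n − 1) given the small group sizes typical
of the assay, and warn below 15 measurements per group. Kinetics tables
summarize F_max per contact time, ascending, and require at least two
distinct times.

## Statistics

Welch's unequal-variance form of the unpaired t-test is used throughout
(group spreads in adhesion data routinely differ, and nothing justifies
pooling). The Wilcoxon rank-sum test is exact by complete enumeration of
rank assignments (midranks, so ties are handled) for n1 + n2 ≤ 12, and
otherwise uses the normal approximation with tie and continuity
corrections; two-sided p doubles the smaller tail, capped at 1. Spearman's
rho is the Pearson correlation of midranks with an exact permutation
p-value for n ≤ 7 and the t approximation above that. Significance stars
follow the inclusive-boundary convention: p > 0.05 n.s; 0.05 ≥ p > 0.01
(*); 0.01 ≥ p > 0.001 (**); p ≤ 0.001 (***). All tests are two-sided; no
multiple-testing correction is applied. Measured type-I error at n = 15
per group over 10,000 standard-normal null replicates: 0.051 (t), 0.047
(Wilcoxon).

## Synthetic data: what it emulates, what it does not

The generators are pure functions of their spec (seed included) and
bit-reproducible.

**Aggregate scenes** render anti-aliased discs or mildly lobed blobs a
fixed contrast (default 0.3) darker than a smooth inhomogeneous
background (level 0.7, gradient amplitude up to 0.3), plus i.i.d.
Gaussian noise clipped to [0, 1]; designated pairs are placed touching to
exercise watershed. The truth label map assigns a pixel to an object when
its centre is inside the boundary; the realized area therefore differs
from the target by at most about one perimeter of pixels. Not emulated:
optical blur, shading that differs between scene and background image,
translucent aggregate interiors, dust with aggregate-like sizes. Passing
recovery tests therefore demonstrates correctness of the measurement
chain, not robustness to acquisition pathologies. The recovery tests
sample object areas from within-class mid-ranges: an object placed on a
class boundary could change class from a one-pixel discretization
difference, which would measure bin placement, not segmentation.

**Sectored colonies** are a disc (default radius 150 px) with a
pixelwise-random mixed core (radius 50 px, emulating the well-mixed
inoculum) surrounded by single-genotype angular wedges whose rim
arc-lengths realize the requested edge monopolization exactly up to pixel
quantization (wedge widths are scaled, not merely counted, so any
fraction is representable); wedge types are interleaved round-robin and
the layout is rotated by a random phase. Channel images are
gain × genotype indicator + autofluorescence + Gaussian noise (defaults:
gains 0.75/0.55, autofluorescence 0.08/0.06, noise 0.02 — chosen as a
bright, well-separated fluorescence regime; the acquisition statistics of
real cameras are not modelled). Not emulated: radially curving sector
boundaries, colony-shape irregularity, uneven illumination, channel
bleed-through.

**Force curves** build a piecewise-linear cycle: approach force ramps to
the contact force (default 1 nN) over the last 0.15 µm; the retract
crosses zero and descends into an adhesion well whose bottom sits exactly
on a sample point at the requested depth, then returns to baseline via
1–5 discrete rupture steps (default 2) completing at 40% of the 4 µm
separation range; linear drift and Gaussian noise are applied on top. By
construction the noise-free curve recovers the true F_max exactly after
baseline correction. Not emulated: cantilever ringing, nonlinear
contact mechanics, worm-like-chain unbinding shapes, thermal drift that
is nonlinear in separation.

**Null groups** are standard-normal paired samples for type-I-error
calibration; defaults (n = 15 per group, 10,000 replicates) mirror the
typical per-group measurement count of the force assay.

## Problem sizes

The shipped tests and the acceptance script use: 1200×1200 px aggregate
scenes with 40 objects; colonies of radius 150 px (images ~340×340);
400-sample force curves, 200 per noisy recovery check; 10,000 null
replicates for calibration; 50 random images for the threshold oracle.
These sizes give discretization and Monte-Carlo error comfortably below
every asserted tolerance while keeping the full suite under a minute of
compute.

## Known limitations

- The global QCAM threshold is user-set by design; no automatic selection.
- Uniform watershed can in principle split a genuinely single, strongly
  non-convex aggregate; `min_seed_distance` controls this trade-off.
- The colony detector assumes one colony per image (largest component).
- The edge ring assumes the colony inradius exceeds the ring depth; very
  small or very elongated colonies raise an error rather than report a
  biased fraction.
- Exact statistical enumeration is bounded (n1 + n2 ≤ 12; n ≤ 7 for
  Spearman); beyond that, corrected approximations are used.
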
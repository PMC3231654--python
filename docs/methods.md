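# Methods

## Problem and model

A camera rides on top of an agricultural vehicle at height `h ≈ 2.15 m`,
pitched `θ ≈ 10°` below the horizontal, recording 720×576 frames at 25 fps
while the vehicle drives along wide-row crops (inter-row spacing
`s = 0.7 m`) at treatment speed (6 km/h ≙ 1.667 m/s, i.e. 66.68 mm of
forward travel per 40 ms frame). Terrain roughness displaces the camera
laterally (sway) by up to ~66% of the inter-row spacing. The pipeline's
job is to (a) remove that sway using the crop rows themselves as tracking
features — there is no horizon and no persistent point features in such
footage — and (b) integrate the stabilized, segmented frames into a
top-down vegetation evidence map of the whole pass.

Assumptions: the ground is locally planar (so a single homography links the
ground and image planes), rows are straight and parallel at known spacing,
the camera pitch is fixed (only lateral sway is compensated; the method
leaves pitch unchanged, and roll is not modelled), and vegetation is
distinctly greener than soil.

## Pipeline stages and parameters

**Segmentation.** Greenness index `gray = clamp(r·R + g·G + b·B, 0, 255)`
with `r = −0.884, g = 1.262, b = −0.311` (coefficients tuned for crop/soil
separation in the literature; pure green saturates at 255, pure red clamps
to 0). The threshold is chosen per frame by Otsu's between-class-variance
criterion — the source method does not fix a threshold value, and a
per-frame adaptive choice is robust to lighting changes. Morphological
opening uses a 10 wide × 15 tall erosion and a 10 wide × 20 tall dilation;
the slightly vertical shapes exploit the vertical continuity of rows: any
blob strictly smaller than the erosion element (weeds project to ≲ 15 px of
vertical extent; with the default geometry every weed of world radius below
~0.09 m) vanishes, while rows — continuous from strip to strip — survive
and are solidified. Anchors sit at index `⌊size/2⌋` of each even-sized
element (scipy's own convention, verified against an exhaustive window
sweep in the tests), and borders are padded with background, so a band of
up to one kernel radius at the image border is not reliable; all
detections happen in strip interiors. Only the bottom `⌊h/2⌋` rows of the
frame are processed (for odd heights the same floor rule applies).

**Row tracking.** The half-frame is divided into 4 equal strips (remainder
rows join the bottom strip; strip centers of a 288-row half are scanlines
36/108/180/252). Per-column mean foreground fill is thresholded at 0.5 —
half-strip occupancy separates continuous rows from sporadic residue — and
maximal runs form blocks; runs separated by gaps of ≤ 3 columns are bridged
first (a sowing irregularity can dip a row's fill just below threshold for
a column or two and split its block). Blocks narrower than 14 px (10% of
the 140 px row spacing) are discarded as weed residue. For each expected
position, the widest qualifying block whose midpoint lies within ±40 px is
selected; the reported center is the fill-weighted centroid of the block,
which equals the run midpoint for flat profiles but suppresses the ±1–2 px
flicker of integer run boundaries. The 40 px window is less than half the
140 px spacing (no row-identity swaps) yet far larger than the ≤ 4 px
inter-frame shifts at 25 fps.

Initialization searches every strip around `W/2` and `W/2 ± 140 px`. Those
expected positions are exact only near the bottom of the frame: under
perspective the outer rows converge by ~23 px per strip going up, so in the
upper strips the fixed window can capture a *neighbouring* row instead.
Initialization therefore validates picks against the straight image line
through the two bottom-most detections of each row and rejects
inconsistent ones (> 10 px off); surviving detections define the row line
and fill the unfound strips. Initialization fails if fewer than two of the
three rows are found in at least two strips. During tracking each strip
searches around its own previous center, so this cross-contamination
cannot recur; missing centers are carried over from the previous frame and
flagged. Lines `x = m·y + c` are fitted by least squares of x on y (finite
slope for vertical rows) over the found centers when ≥ 2 exist, else over
all four carried centers. Centers are kept strictly ordered
left < middle < right per strip; a found center that breaks the ordering
is dropped (the one that moved farthest from its previous position).

**Stabilization statistic.** The signed distance between the central-row
line and the image vertical centerline, evaluated at scanline y = 215 of
the half-frame (a parameter: no strip center naturally sits there, so the
evaluation scanline is exposed rather than guessed). 93 px of deviation at
140 px spacing is 66% of a row gap — the scale of sway the method absorbs.

**Inverse perspective mapping.** Sources are the intersections of the two
outer row lines with the top and bottom strip scanlines (the configured
scanlines are used regardless of found/carried status); targets are the
corners of a rectangle of width 2s, horizontally centered in the output.
The homography is estimated by the direct linear transform on the 4
correspondences with Hartley normalization of both point sets for
conditioning, rejecting configurations with more than two collinear points,
and canonicalized so the largest-magnitude entry is +1. Warping is
inverse-mapped nearest-neighbour (the input is a binary mask; interpolation
would create fractional values). Horizontal metric scale is
`mm_per_px_x = 5`; vertical scale is calibrated from the camera geometry —
the ground distance between the top and bottom strip scanlines stands in
for measuring an object of known length in the scene (`rowmap calibrate`,
≈ 20 mm/px for the default rectangle height of 260 px). The bird's-eye
canvas is 560 px (2.8 m) wide so that the three tracked rows stay inside
it over the full ±0.46 m sway range.

**Mapping.** The map reference advances exactly `1000·v/fps` mm per frame,
kept in floating millimeters and rounded only at cell lookup (no drift
over long passes). Every white bird's-eye pixel inside the calibrated
rectangle maps to a world cell; a cell is incremented at most once per
frame however many pixels land in it — the count is "in how many frames
was vegetation seen here", supported by the bounded 0–17 count range a
~1.1 s dwell produces. Cells are 10 mm squares (see design notes).
Thresholding keeps counts ≥ `round(fraction·max)` with round-half-away
(0.25 × 17 → 4); rendering maps the maximum count to 255.

**Row straightness.** Quality of a finished map is scored per row band:
occupied lateral columns of the thresholded map split into maximal runs at
the empty inter-row gaps; the n most massive bands (map borders may clip
further neighbour rows to slivers) are each reduced to one count-weighted
lateral centroid per forward cell row, a line is fitted, and the RMS
perpendicular residual is reported in cells. A straight mapped row scores
~0; a row meandering as a sinusoid of amplitude A cells scores ~A/√2. If
the gaps have closed (bands touching), a weighted 1-D k-means fallback
splits the cells instead.

## The synthetic generator

The generator emulates the imaging conditions the pipeline assumes: 5
parallel rows 0.7 m apart centered on the vehicle path, plants as
anti-aliased ellipses (canopy width 0.2 m, ~15 plants/m so canopies
overlap into a continuous row, 5% sowing gaps), weed blobs of ~6 cm
radius at 0.3/m² in the inter-row space, brown-gray textured soil chosen
so the greenness index stays at 0 on soil and well-separated (~175) on
vegetation, and a pinhole camera at 2.15 m / 10° pitch. The world is
rasterized once on a 10 mm grid from the scene seed; each frame is rendered
by back-projecting 2×2 subpixel rays onto the ground plane, so imagery,
per-frame true row-center pixels (projections of the world row centerlines)
and occupancy labels all share one geometry, and output is bit-identical
for identical seeds. The per-pixel truth label is the strict majority
(> 2 of 4) of the same subsamples, ties to soil, so a labelled vegetation
pixel is at least 75% vegetation-coloured — segmentation recall is
measured against the rendering itself.

The focal length is not a measured quantity; the default (≈ 1047 px,
~38° horizontal field of view) is solved in closed form so that 0.7 m
projects to exactly 140 px at the bottom-strip scanline, making the
method's 140 px search arithmetic exact at the reference geometry.

Not emulated: photorealism, shadows, plant growth, pitch/vibration motion,
and camera roll (the trajectory type carries an optional roll channel but
rendering rejects non-zero roll). Lens distortion is absent — the ideal
pinhole the IPM derivation itself assumes. Consequently, passing tests
show geometric and algorithmic correctness under the stated model, not
robustness to optics, lighting or canopy phenomena absent from the
simulation.

**Sway model.** Default terrain sway is a sum of two sinusoids (periods
120 and 37 frames, amplitudes 0.25s and 0.08s) plus 5 mm Gaussian jitter.
For the stabilization benchmark the sway is a single slow roll: amplitude
0.66s and period twice the 300-frame pass. The period matters physically: a
field cell stays in the camera's view for ~78 frames (5.2 m of visible
ground at 66.68 mm/frame), and any sway component faster than that dwell
is averaged out of *every* accumulated map, stabilized or not; a sway
cycle slower than the pass is what produces the meandering rows seen in
unstabilized maps, which is the phenomenon the comparison measures.

## Design notes and numerical choices

- **Map cell size 10 mm.** A 20 mm cell also maps weeds adequately, but
  the straightness comparison needs the sway amplitude to be large in
  cell units: the least line-absorbable sway (one half-period over the
  pass) leaves an RMS residual of ~0.31·A after the band's line fit, so at
  0.46 m amplitude only a ≤ ~14 mm cell resolves a double-digit residual
  while stabilized maps stay well under one cell. 10 mm resolves both
  regimes (and weeds at 12 cells diameter).
- Coordinates are 0-based, origin top-left, x rightward, y downward, all
  intervals half-open; pixel centers sit at integer coordinates and the
  principal point at the exact image center.
- `AdvanceModel.from_kmh` rounds to mm/s (6 km/h → 1.667 m/s), the
  precision at which such speeds are quoted; 1.667/25 gives the 66.68 mm
  advance used everywhere.
- The map threshold rounds half away from zero so fraction 0.25 of
  maximum 17 gives exactly 4.
- Degenerate inputs raise structured errors: empty frames, blank first
  frames (initialization), swapped/crossing row lines (degenerate
  trapezoid), > 2 collinear correspondences, non-invertible homographies,
  empty maps.
- Problem sizes in the test suite: unit tests run on a 20-frame synthetic
  sequence; the end-to-end stabilization comparison uses one 300-frame
  pass (20 m of travel), rendered once and shared across tests.

## Known limitations

- Three central rows only; curved rows, row ends and headlands are out of
  scope, as are predictive (Kalman-style) trackers.
- Heavy weed cover that bridges the inter-row space would defeat both the
  width-based block classification and the straightness band splitting;
  the generator's weed rate keeps weeds sparse, as does the method's
  intended use (mapping before treatment in maize).
- The unstabilized/stabilized comparison depends on the sway spectrum
  relative to the viewing dwell (see above); very fast vibration is
  invisible to the map and is not compensated.
- Vertical map scale relies on the calibration helper (exact in
  simulation); on real footage it must come from a measured object, and
  errors there stretch the map along the travel axis.
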
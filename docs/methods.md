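# Methods

This note documents the models, numerical choices and known limits of
`zfswim`. Everything quantitative below is computed by the test suite
or by `scripts/acceptance.py`; nothing is asserted that the code does
not measure.

## Segmentation and tracking

The background model is the per-pixel temporal median of the whole
clip. This assumes a static tank and a fish that keeps moving: a pixel
must be fish-free in more than half the frames for its median to be
background. For an even number of frames the *lower* median (sorted
index ⌊(n−1)/2⌋) is used so the background remains an actually observed
8-bit intensity. The model is an order statistic, hence exactly
invariant to any permutation of the frames.

Detection thresholds the absolute difference image at a global value
(default 25/255, chosen for a dark fish in a lighter tank and exposed
in `RunConfig.threshold`), applies one 3×3 binary opening then closing
(drops sensor speckle without eroding the thin tail), labels components
with 8-connectivity (thin diagonal tail segments stay connected) and
keeps the largest component of at least `min_area` px (default 50).
Ties go to the component whose first foreground pixel comes earliest in
row-major order, for determinism. The centroid is the unweighted mean
of foreground pixel coordinates; coordinates are 0-based, origin at the
top-left pixel center, x rightward, y downward. A fish touching the
image border is segmented with a logged warning, since the centerline
endpoints may then be clipped. A clip in which more than half the
frames yield no detection aborts with a tracking error.

## Posture model

The outer boundary is an ordered chain of boundary pixel centers from
Moore-neighbor tracing (holes are filled with a warning). On this
convention a 10×4 px rectangle has perimeter exactly 24 and a
rasterized disk of radius 20 measures within ~2.5% of 2πr.

The midline is the morphological skeleton (topology-preserving
thinning) of the silhouette, restricted to its longest
endpoint-to-endpoint geodesic — Dijkstra over 8-connected skeleton
pixels with Euclidean step costs — which removes fin and noise spurs
without a pruning parameter. Silhouettes with elongation (square root
of the principal-axis variance ratio) below 1.5 have no meaningful
midline and raise a per-frame posture error; the frame is skipped, not
fatal.

The raw skeleton path zigzags at the pixel scale. It is replaced by a
cubic smoothing spline over arc length with residual budget
`s = n·(0.5 px)²`. The 0.5 px scale matches 8-connected quantization
noise; on the zero-noise synthetic cohort this choice removes a
4–5° staircase floor in the discrete curvature (a 5-point moving
average, tried first, left per-cycle max-curvature errors up to +39%
at the thin tail; the spline keeps all per-cycle errors within ±13%).
Body-scale bends are essentially untouched: the spline attenuates the
synthetic wave's curvature peak by a few percent at most.

Head/tail assignment: on the first frame the head is the end with the
larger mean distance-transform value over the 10% of arc length nearest
the endpoint (adult zebrafish are widest near the head, narrowest at
the caudal peduncle); exact ties fall back to the endpoint with smaller
x, then smaller y. Subsequent frames keep the orientation consistent
with the previous posture (smaller summed endpoint-to-endpoint
distance), which overrides the width heuristic.

Control points are sampled at arc lengths `k·L/(n−1)`, `k = 0..n−1`
(default n = 20), by linear interpolation along the smoothed polyline;
the first and last points coincide with the skeleton endpoints and
`L` is the polyline arc length. Note that a morphological skeleton
terminates roughly half a body width short of the silhouette tips, so
`L` is the skeleton length, not the snout-to-fin-tip length; all
ratios (tail offset) use the same `L`, so this is a consistent
convention rather than a bias.

Limitation: thinning is not rotation-equivariant. Under an exact
90-degree raster rotation the recovered control points match the
rotated originals to ~1 px on average, but the tail endpoint can shift
~2 px and the shift spreads linearly through the arc-length resampling;
the curvature *peak* of a re-extracted rotated silhouette can move by
~3%. The measurements themselves (curvature, tail offset) are exactly
invariant when the posture is transformed, and the full chain is
exactly invariant under whole-pixel translation.

## Kinematic measurements

Curvature at interior point `i` is the absolute wrapped difference
between the directions (atan2, degrees, range (−180, 180]) of the two
midline segments meeting at `i`. Unsigned values are used because all
downstream profiles compare bending magnitudes. The two endpoints copy
their nearest interior neighbour so the profile has exactly n entries
and the cycle matrix keeps n rows. The sum of interior values
approximates the total turning of the midline (within 10% for C-shaped
postures bent through 60–170°).

Tail offset is `T/L` with `T` the Euclidean distance from the last
control point to the *mask* centroid. "Center of the body" could also
mean the midline midpoint; the mask centroid is used because travel
distance tracks the same centroid — one center definition throughout.

Travel distance defaults to the summed frame-to-frame centroid path
over the cycle span ("distance traveled" read as path length);
start-to-end net displacement is available via
`RunConfig.travel_mode = "net"`. Runs of at most 2 consecutive
missing detections are bridged by linear interpolation; longer gaps,
or gaps at the cycle boundary, reject the cycle.

## Cycles, smoothing, group statistics

A body-waving cycle is normalized to `cycle_target_length` frames
(default 30). Longer spans are subsampled at
`index_k = start + round(k·(len−1)/(target−1))` with
round-half-away-from-zero, duplicates shifted to the next free index
(the selected frames are then not contiguous); shorter spans are
extended with contiguous frames split as evenly as possible around the
span, odd frame after, borrowing from the other side at video bounds.

Smoothing is a 4th-order Butterworth applied forward-backward
(zero phase) with even-reflection padding — measured on the short 20-
and 30-sample profiles used here, even reflection keeps edge
transients negligible where the default odd padding lets a
Nyquist-frequency artifact survive at the boundary untouched. Cutoffs
are normalized so 0.5 = Nyquist; defaults 0.2 (spatial, along the 20
body locations) and 0.15 (temporal, along the 30 cycle frames), both
config-exposed. They were chosen by inspecting Fourier magnitude
spectra of synthetic-swimmer curvature and tail-offset series — the
`inspect-spectrum` subcommand reproduces that inspection for any
clip — such that the body-wave band passes and pixel-scale noise is
rejected. Filter ringing can produce small negative curvature values;
these are clipped to zero to preserve the unsigned-curvature
convention. Per-frame tail-offset traces are smoothed with the
temporal filter.

Automatic cycle detection (used when no manual annotation is given)
splits the clip at maxima of the smoothed tail-offset trace — the body
is straightest exactly when the tail offset peaks — with a minimum
prominence (`peak_prominence`, default 0.002) and endpoint maxima
counted. It needs at least two target lengths of signal.

Group profiles are elementwise means over all cycles of all fish in a
group, following the pooled-cycles convention; per-fish averaging first
is available (`per_fish_averaging`) but is not the default. Both
orders of extremum-vs-average are reported and labelled distinctly:
`metric_mean` averages per-cycle extrema (used for the comparisons),
`profile_extrema` takes extrema of the averaged profile.

The group comparison is a classical equal-variance two-sample Student
t-test, two-sided, against the wild-type group, one test per metric at
α = 0.05 with no multiple-testing correction (three tests per group —
noted here deliberately; Welch's correction is available via
`equal_variance = False`). Zero-variance degeneracies are resolved
explicitly: equal means → t = 0, p = 1; unequal means → significant
with p reported below the smallest positive float. The implementation
is checked against `scipy.stats.ttest_ind` and calibrated on 10 000
seeded null replicates (type-I error 0.049 at α = 0.05). Group metric
means are also divided by the wild-type mean, making wild-type 1 by
construction.

## Synthetic swimmer

The generator exists to give every pipeline stage an analytic ground
truth. In the body frame (arc coordinate u, head 0 → tail L):

    y(u, t) = stiffness · A · (u/L) · sin(2π(u/(λL) − f·t))

a wave traveling head-to-tail under a linearly tail-growing envelope
(the carangiform pattern: the head barely yaws, the tail sweeps
widest). The body is transported rigidly at constant speed along its
heading; translation speed scales with the stiffness factor because
undulatory thrust scales with tail-beat amplitude — this single knob
(`stiffness`, default contrast 1.0 vs 0.5) yields the stiff phenotype's
full signature: lower curvature, higher tail offset, shorter travel per
cycle. The rendered body is a union of disks along the midline with a
piecewise-linear half-width profile (blunt 6 px head, 7 px trunk,
1.5 px caudal peduncle at the default 140 px body length), plus
optional seeded Gaussian intensity noise (default SD 2 on a
140-intensity-unit contrast). Defaults mirror the target recording
conditions: 480×640 px, 250 frames/s, ~140 px adult fish, 4 Hz beat,
200 px/s (~1.4 body lengths/s).

A body-waving cycle corresponds to *half* a beat period — the shape at
t + 1/(2f) is the mirror image of the shape at t, so each half period
is one straight→bent→straight episode. At the defaults that is ~31
frames, matching the 30-frame normalization target.

Ground truth per frame: the 20-point arc-uniform midline, its discrete
curvature (same definition as the pipeline's), the mass centroid of the
variable-width strip, the tail offset from that centroid, and the arc
length. Clips are sized so the fish travels at least 2.2 body-passage
times (`frame_count ≥ 2.2·L/speed·fps`); below ~2 passage times the
temporal median is contaminated along the swim path and segmentation
degrades — this is a property of median backgrounds generally, not of
the generator.

What the generator does **not** emulate: hydrodynamics (the kinematics
are prescribed, not emergent), turning or burst-glide behaviour
(constant heading and speed), shadows, reflections and water-surface
ripple, partial occlusions, and multi-fish scenes. Passing the
recovery tests therefore demonstrates that the measurement chain is
accurate for a clean single swimmer; it does not certify segmentation
robustness against real-tank imaging artifacts, for which the
threshold, morphology and cutoff parameters are exposed.

## Problem sizes used in the checks

Ground-truth recovery runs 2 fish × 3 cycles, zero noise, at full
480×640/250 fps scale; measured errors: max curvature within ~8% of
truth (bound 15%), min tail offset within 0.003 absolute (bound 0.03),
travel distance within ~6% of effective speed × duration (bound 10%).
The phenotype contrast uses 10 cycles per group (2 fish × 5 cycles,
noise SD 2), giving relative stiff-group means ≈ 0.58 / 1.06 / 0.51
for max curvature / min tail offset / travel distance, each contrast
p < 1e-15. Unit tests run a downscaled swimmer (70 px body, 160×320 px,
100 fps) chosen to exercise identical code paths at a fraction of the
cost.
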
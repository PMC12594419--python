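# Methods

This note documents the models, conventions, parameters and limitations of
`battrack`. It is the package's own account of its science; every number
quoted here is computed by the test suite or the demo pipeline, not assumed.

## Coordinate conventions and camera model

The world frame has its origin at the turbine tower base, x east, y north,
z up, in meters; the ground is z = 0 (right-handed). Headings are compass
azimuths (0° = north), tilt is elevation above the horizon. The camera is
an ideal pinhole: pixel origin top-left, x right, y down, principal point
at the image center, no lens distortion, no radiometric calibration
(intensities are arbitrary "sensor counts", not temperatures).

Defaults describe the deployment geometry being emulated: two cameras 75 m
from the tower on opposite sides, looking back at it, 1.5 m above ground,
tilted 15° up, 35 mm lens at 30 fps. The sensor format (32 × 24 mm) and
resolution (640 × 480, tests use 320 × 240) are package choices, set so
the two-camera union footprint covers a ~50 × 100 m ground rectangle
around the tower; the geometry test measures 5 179 m² against the nominal
5 000 m². All of these are config-exposed, not asserted as any particular
hardware's values.

The ground footprint is the view frustum intersected with z = 0, clipped
to a [near, far] range band (defaults 5–100 m). It is computed by dropping
rays through a dense sampling of the image boundary onto the ground
(rays at or above the horizon are extended to a sentinel range and cut by
the far clip); if no boundary ray meets the ground the footprint is empty
and flagged. Tower occlusion is modeled in 2-D: the ground region hidden
behind a 2.5 m-radius cylinder — the wedge between the sight-line tangents
plus the tower disc — intersected with the footprint. This reproduces
"carcass found in the tower shadow" accounting without 3-D ray casting.

Nights run sunset-to-sunrise and belong to the evening's calendar date.
Sunset/sunrise are fixed clock times (19:30 / 07:00 by default) rather
than an ephemeris: the cameras being emulated recorded with ≥ 2 h twilight
margins, so a fixed envelope is sufficient for night attribution; both
times are parameters. Outage intervals are half-open [start, end).

## Fall physics

A carcass is a point mass under gravity and quadratic drag:

    m dv/dt = m g_vec − c |v − w| (v − w)

with lumped drag constant c (kg/m) and horizontal wind w. Defaults:
m = 12 g (Brazilian free-tailed bat scale, the dominant species at the
kind of site being emulated) and c = mg/v_t² for a terminal speed
v_t = 10 m/s — a deliberate stand-in, since no measured drag constant for
a bat carcass is available to us. Tumbling/fluttering is optionally
emulated by per-step Gaussian perturbation of c (fractional SD 0.15 in the
corpus generator). Integration is fixed-step RK4 at dt = 1/fps; ground
impact is located by linear interpolation of the final step (O(dt²), ~2 ×
10⁻⁴ s at 30 fps). For a pure vertical drop the speed must follow
v_t·tanh(g t / v_t); the test suite verifies agreement to better than
1 × 10⁻⁴ relative (measured ~2 × 10⁻⁸).

## Flight and insect model

Flying objects follow a correlated random walk, one step per frame:
heading accrues Gaussian turn increments (SD 0.15 rad/step for bats, 0.6
for insects), speed is resampled uniformly in a range (3–8 m/s bats,
0.3–2 m/s insects), altitude takes Gaussian jitter reflected into a band.
This is deliberately phenomenological: it produces tracks whose kinematic
statistics separate flight from ballistic falls, which is all the
classifier contract requires. It does not model wing-beat articulation,
thermals, or pursuit behavior.

## Rendering

Objects render as isotropic 2-D Gaussian intensity blobs; FWHM equals the
apparent angular size of the body (0.30 m for bats, 0.02 m for insects)
with a 0.7 px sigma floor; peak amplitude is constant in sensor counts
(40 bats, 15 insects) over a static background (vertical gradient plus a
warm tower column, which the background model absorbs) with additive
Gaussian sensor noise (SD 2.0). There is no radiometric model, no rain or
clutter, and no occlusion of rendered objects by the tower column.

What passing tests on these scenes do and do not show: they validate the
*chain* — detection finds what was rendered, tracking reassembles the
trajectories, classifiers separate the motion classes, matching and
accounting reconcile exactly. They do not certify field performance on
real thermal video, where backgrounds move (vegetation, clouds), bats
articulate, and object appearance varies with temperature contrast.

## Detection

Per-pixel running Gaussian background: cumulative mean/variance during a
30-frame warmup, then exponential moving averages with learning rate 0.05.
Foreground is |frame − mean| > k·√(var + ε) with k = 4 noise standard
deviations (parameterizing in SD units transfers across noise levels) and
ε = 10⁻⁶ as a dead-pixel variance floor. Detected foreground (dilated by
1 px) is excluded from the background update; otherwise a slowly-moving
warm object inflates the local variance estimate and intermittently
suppresses its own detection. Blobs are 8-connected components with
area ≥ 2 px; centroids are intensity-weighted by the absolute deviation;
width/length are extents along the component's principal axes. At k = 4
and min_area = 2 the measured noise-only false-detection rate is below
0.1 per 320 × 240 frame. Composite images are max-intensity projections of
detection pixels over the background with centroid marks; the review
window is configurable (5 or 10 minutes are the conventional choices).

## Tracking

Frame-by-frame gated assignment: each open track predicts its next
position (constant velocity once it has two detections; raw proximity for
the first link), candidate pairs within 20 px are matched by
minimum-total-distance bipartite assignment (`scipy`
`linear_sum_assignment`), unmatched detections open tracks, tracks
unmatched for more than 3 frames close, and ties break deterministically
by (track id, detection id). Per-frame optimal assignment (rather than
multi-frame optimization) keeps the linker testable against an exhaustive
oracle, which the suite runs on ≤ 12-detection instances. Pruning removes
tracks with < 5 detections or total path < 5 px; pruning is a separate
step so detection counts always reconcile exactly. All gates are
config-exposed stand-ins — the field systems' values are not public.

Track features (pixel units, finite differences over actual timestamp
gaps): mean/max/SD speed and acceleration magnitude, mean detection area,
mean width/length ratio, net vertical displacement (image-down positive),
path straightness (net/total, defined 0 for a stationary track), descent
fraction (fraction of steps moving image-down), duration. Descent fraction
and straightness are additions beyond generic velocity/size statistics;
they are what make fall-vs-flight nearly separable. Tracks with only two
detections zero-fill the acceleration statistics and carry a flag.

## Classification

Two seeded random forests (200 trees, standard-scaled inputs) on the fixed
feature vector: object class (bat/insect; the schema admits bird, blade,
other when labels exist) and, for bat tracks only, activity vs fatality.
The fatality class is trained on physics-simulated fall tracks because
falls are rare events; activity comes from simulated flight. Class
weighting ("balanced") guards residual imbalance. A track is flagged as a
fatality when its fatality probability reaches the threshold (default
0.5); threshold 1.0 disables flagging, and flag counts are monotone in the
threshold. On the default 150/150/150 corpus both stages reach 100 %
held-out accuracy; the acceptance floor is 90 % (object) and 95 % (fate).
Machine flags are an attention mechanism, not a verdict: the review-queue
export (composite image per flagged track) represents the manual
confirmation step that field practice requires.

## Activity metric

Each bat-class detection represents one frame = 1/fps seconds of bat
presence, so activity over a period is (detection count)/fps
"bat-seconds"; fps is a parameter with default 30. Counting is exact over
half-open bins that tile the night; out-of-range detections raise rather
than disappear. Bat-seconds keep full float precision internally and round
to 0.1 s for display. Hourly profiles index hours from sunset (hour 0) per
night; re-aggregation conserves totals exactly.

## Carcass matching and evaluation

A carcass a days old discovered on day D died during night D − 1 − a
(fatalities are nocturnal; age 0 means the night before discovery), so an
age range [a_min, a_max] spans the contiguous nights D − 1 − a_max …
D − 1 − a_min. Accounting precedence is outside-FOV → occluded →
camera-nonoperational → matching; a carcass is occluded only if *every*
camera whose footprint contains it has it in its tower shadow, and
nonoperational only if no seeing camera recorded during any window night.
This ordering is a package convention chosen to make the categories
partition the records exactly.

Matching is one-to-one maximum-cardinality assignment between flagged
tracks and carcasses, eligibility = (track timestamp inside the carcass
window) ∧ (ground distance ≤ 15 m); among maximum matchings the smallest
total distance wins, then earlier tracks. The 15 m default radius is a
judgment call for "same area"; MP is provably non-decreasing in both the
radius and the window width, and the tests verify optimality against
brute-force enumeration on ≤ 8 × 8 instances. A track's ground position is
its final detection back-projected through the camera onto z = 0 —
uncertainty is not propagated, and the depth direction is poorly resolved
from a ground-level camera (near the horizon, 1 px of image error maps to
~10 m of range error at 75 m standoff), which is the dominant source of
missed matches in the demo.

Rates: matched = MP/(MP+CN)·100, missed = CN/(MP+CN)·100, false detection
= CFP/(MP+CFP)·100 — conventional sensitivity, false-negative-rate and
false-discovery-rate forms. Zero denominators yield an explicit
"undefined", never a division error; displayed rates round to 0.1 %.

## Pipeline, seeds and problem sizes

One top-level seed drives everything; object generation fans it out with
`SeedSequence.spawn`, so increasing one class count never reshuffles
earlier objects. Every stage output carries a configuration hash and the
pipeline refuses to mix outputs from different configurations; the run
manifest reconciles record counts across stages.

Problem sizes were chosen to keep a full check fast on a single CPU while
remaining statistically meaningful: test scenes render at 320 × 240 over a
few hundred frames; the classifier corpus is 150 objects per class; the
end-to-end flag-rate check uses 12 independently-seeded fall scenes; the
accounting fixture carries 40 carcass records. All sizes scale up through
the config without code changes.

## Known limitations

- Synthetic-only validation: no moving vegetation, rain, or multi-modal
  backgrounds; the background model is single-Gaussian per pixel.
- No species identification, and tracks are not individuals (one bat can
  produce many tracks).
- Single-camera processing: the two per-turbine cameras are evaluated
  geometrically (footprints, occlusion) but tracks are not fused or
  triangulated across cameras.
- Ground-position depth error as described above; matching radii below
  ~10 m are not meaningful for a 75 m standoff camera at 320 × 240.
- No bias-corrected mortality estimation (searcher efficiency, carcass
  persistence); the evaluation stops at MP/CFP/CN and their rates.
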
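# Methods

This note documents the models, conventions and numerical choices behind
`wormbox`: what each analysis computes, what the synthetic-data generator
emulates, and where the design was genuinely open.

## Coordinate and box conventions

Boxes are axis-aligned rectangles in continuous image coordinates (pixels,
origin top-left, y downward) with strictly positive area. Pascal VOC XML as
written by labelImg stores 1-based *inclusive* integer pixel coordinates: an
object spanning pixels `xmin..xmax` is `xmax - xmin + 1` pixels wide. On
read, these widen to the continuous interval `[xmin - 1, xmax]` per axis;
the writer inverts this exactly, so integer round-trips are bit-faithful.
labelImg itself does not document whether its coordinates are 0- or 1-based;
the 1-based-inclusive reading is this package's fixed convention, not a
claim about any particular annotation set. COCO bboxes `[x, y, w, h]`
convert to corner form `[x, y, x+w, y+h]`. Readers reject non-positive
extents rather than repairing them: a degenerate box in an input file is
evidence of an upstream bug, and silently "fixing" it would corrupt IoU and
AP downstream.

All confidence and IoU comparisons are inclusive (`>=` at the threshold).

## Detection evaluation

Matching is greedy per frame and per class in descending-confidence order
(ties broken by input order, which is stable): each detection claims the
unmatched ground truth of highest IoU and is a true positive iff that IoU
meets the threshold; extra detections on an already-claimed ground truth are
false positives; unclaimed ground truths are false negatives. This is the
standard Pascal-VOC protocol. Average precision pools the confidence-ranked
TP/FP flags over the whole dataset, builds the cumulative precision–recall
curve, replaces each precision with the maximum precision at any equal or
higher recall (the monotone envelope — "all-point" interpolation, not the
older 11-point variant), and sums recall increments times envelope
precision. Default working points: worms at confidence 0.5 / IoU 0.5; eggs
at confidence 0.01 / IoU 0.3, because eggs are only a few pixels wide and
small localization errors move their IoU a lot.

Both AP and the two-sample KS statistic are checked in the test suite
against deliberately naive re-implementations (exhaustive PR enumeration;
double-loop ECDF evaluation) to 1e-12.

## Kinematics

The track of one animal is the per-frame centroid (box midpoint) of the
selected detection; frames without a qualifying detection are explicit gaps,
and no derived quantity is ever interpolated across a gap. Two selection
policies exist: `highest_confidence`, and `nearest_to_previous`, which
prefers the qualifying detection closest to the last known position and
thereby rejects sporadic false positives far from the animal's path.

Displacement over an interval is the Euclidean centroid distance in mm
(via the rig calibration `mm_per_pixel`); linear velocity is displacement
divided by the interval, assigned to the left endpoint so velocity aligns
with the state label of the interval's start. Moving averages are centered
and truncated at series ends *and at gaps* — a centered window avoids phase
lag relative to state labels, and refusing to span gaps keeps separate
detection runs independent. Downsampling keeps samples congruent to the
first retained timestamp modulo the target interval, with no interpolation.
The native frame interval always comes from the calibration config and is
never inferred from data, to avoid silent unit errors.

## Roaming/dwelling classification

Angular velocity at time t is the three-point turn magnitude: the absolute
wrapped difference between the heading of `c(t) − c(t−Δ)` and the heading of
`c(t+Δ) − c(t)`, divided by Δ, in deg/min. It is undefined — not zero —
wherever a centroid is missing or a displacement has zero length, because a
stationary animal has no heading; undefined timestamps propagate into the
state series and are excluded (and counted) in accuracy scoring.

Classification at 1-minute sampling uses a single threshold: angular
velocity below 90 deg/min is roaming, at or above it dwelling. The boundary
assignment at exactly 90 is arbitrary; dwelling was fixed for consistency
with the package-wide inclusive-threshold rule. A 2-D linear rule (a
configured line in linear×angular velocity space, on-or-above = dwelling)
supports labeling ground-truth states from higher-frequency reference
data; its parameters must always be
supplied explicitly — there is no hidden default for another lab's split.

## Egg-laying phenotypes

Egg positions are detection-box centroids. Arenas wider than one field of
view are imaged as overlapping tiles, so one physical egg can appear in
several images; observations from *different* tiles within one merge radius
are collapsed by single linkage, keeping the highest-confidence member,
while same-tile neighbors are never merged (two nearby detections in one
image are two eggs). The default merge radius is one egg diameter
(~50 μm / `mm_per_pixel`): eggs are rigid bodies, so two distinct eggs
cannot sit closer than about one diameter, while duplicate observations of
one egg in two tiles land within localization error of each other.

Rates: eggs at the first snapshot (default 2 h after transfer) accumulated
since transfer, so `rate1 = count_t1 / t1`; the second window gives
`rate2 = (count_t2 − count_t1) / (t2 − t1)`. A decreasing count is logged
and the second rate floored at zero. The lawn preference score is
`(eggs_on − eggs_off) / (eggs_on + eggs_off)`; boundary eggs count as
on-lawn (inclusive rule). Distribution comparisons use the two-sample KS
test (scipy), with the exact small-sample null when available.

## Aging movement decline

Per video, the movement score is `1 − IoU` between the worm's bounding box
in the first and the last frame — exactly those two frames, not a
multi-pair average. Egg-cluster boxes carry a different class label and are
excluded by the track-assembly step, so passive egg-cluster movement never
contaminates the worm score. The mask-based pixel-change metric is
`Σ|m1 − m2| / ((Σm1 + Σm2)/2)` on binary masks, bounded in [0, 2] and zero
iff the masks are identical.

Cohorts summarize to a per-individual score matrix over age plus per-age
mean and SEM (sample SD / √n; a lone individual reports SEM 0 with n = 1
rather than NaN). Food levels are compared by KS on scores pooled from ages
at or after the intervention age (day 2 of adulthood by default, when the
dietary-restriction shift happens). The comparison unit defaults to
per-video scores; per-individual time-averages are available via
`unit="per_individual"` since either unit is defensible.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with the hidden
truth needed for recovery tests. It emulates statistical structure, not
images: there is no rendering, no occlusion, no illumination model, and
detector errors are drawn i.i.d. rather than correlated over time as a real
detector's failures are. Passing recovery tests therefore demonstrates that
the *analysis machinery* is correct under the stated noise models — not
that any particular detector reaches a given accuracy on real plates.

**Trajectory.** Discrete steps of the native frame interval dt. A two-state
Markov chain (per-minute switch probabilities, converted to the step scale
as `1 − (1−p)^dt`) selects roaming or dwelling. Each step the animal draws
an instantaneous turn rate ω ~ N(0, σ_state) in deg/min and a truncated-
normal speed, rotates by ω·dt, then advances speed·dt. The turn drawn at t
applies to the step *leaving* t, so at native sampling the measured
three-point angular velocity at t is exactly |ω(t)| under the labeling
state. The single-timestamp observation density per state is then a folded
wrapped normal, and the Bayes-optimal classification accuracy of the model
is computable by quadrature (`bayes_accuracy`), giving an analytic yardstick
for the 90 deg/min classifier. Because consecutive turn rates are
independent, coarser sampling averages them and shrinks the measured
angular velocity for both states, collapsing their separation — the
qualitative signature of lost roaming/dwelling separability at low sampling
frequency. An alternative diffusive-heading model (per-step turn sd scaling
with √dt) was rejected: under it a fixed 90 deg/min threshold *improves* as
sampling coarsens, the opposite of the behavior the analyses assume.

Default state parameters: roam turn-sd 75 deg/min, dwell turn-sd
225 deg/min, switch probabilities 0.10/min (roam→dwell) and 0.08/min
(dwell→roam), stationary roaming occupancy 4/9; roam speed 0.15 ± 0.05
mm/min, dwell speed 0.02 ± 0.01 mm/min at 0.01 mm/pixel. These were
calibrated once, by quadrature on the observation densities, so that the
90 deg/min split sits within ~0.7 percentage points of the Bayes boundary —
informative but imperfect — while keeping roaming the faster, low-turning
minority state. With a much tighter roam turn distribution the Bayes
boundary migrates far below 90 deg/min and a 90 deg/min rule would be
grossly suboptimal, which is incompatible with treating it as the working
classifier. Arena 2000 px with reflective walls; trajectories start at the
center so wall reflections (which perturb headings) are rare at default
durations.

**Growth.** Box area follows a logistic ramp in log-area from 124 px²
(a typical smallest tracked animal) to 5× that over the scenario, endpoints
hit exactly; the box keeps a 2:1 aspect ratio around the centroid.

**Detector noise.** True boxes are jittered in center (Gaussian, default
1 px) and size (5% fractional), dropped with miss probability 0.05, and
supplemented by Poisson false positives (0.05/frame) at uniform positions;
confidences are Beta(8,2) for true and Beta(2,5) for false detections. The
`NOISELESS` preset (no jitter, no misses, no false positives, confidence 1)
realizes the perfect-detector identity AP = 1.

**Eggs.** Bursts arrive as a Poisson process at `rate / mean_burst_size`
per hour so the expected egg rate equals the configured 6 eggs/hr (inside
the commonly reported 4–10 eggs/hr band); burst sizes are geometric with
mean 2; eggs scatter around the worm's position at the burst time with
12 px spread. Each egg lands on the circular lawn with probability
`p_on = 0.8`, enforced geometrically so flag and position always agree, and
egg centers keep a minimum spacing of about one egg diameter (rigid
bodies), which is also what keeps distinct eggs out of each other's dedup
radius. Snapshots at 2 h and 5 h are tiled 2×2 with 10% overlap; an egg
appears in every tile covering it, so the double-count structure removed by
dedup is real. Brood is capped at 300, a hermaphrodite's typical total.

**Aging.** Target movement `m(age)` follows a logistic decline from 0.9 to
0.05 with midpoint day 6 at high food (OD600 10) and day 9 under dietary
restriction (OD600 2.5), scale 2 days, plus N(0, 0.08) individual noise
clipped to [0, 1]; 30 individuals per food level at ages 0–14 days. The
emitted first/last boxes are equal rectangles offset horizontally by
`dx = w(1 − IoU)/(1 + IoU)` so their IoU is *exactly* `1 − m` in continuous
coordinates (a bisection oracle confirms the closed form); masks are the
boxes rasterized to a pixel grid, so mask-based pixel change is consistent
with, but slightly coarser than, the continuous box metric.

Every output is a deterministic function of (config, seed); each
sub-simulator draws from its own child stream of the master seed, so e.g.
adding egg simulation to a run never perturbs the trajectory.

## Problem sizes

The recovery analyses use 5 × 2000-minute trajectories for the state
classifier (≈10⁴ labeled timestamps), 10 × 400-minute 1-s-resolution
trajectories for the sampling-coarseness sweep, 40 egg scenarios of 5 h
each, and 50 aging cohorts of 30 individuals × 8 ages × 2 food levels.
These sizes put Monte-Carlo error well inside the tolerances being checked
while keeping a full run on one CPU in minutes.

## Known limitations

- Single-animal tracking only; no identity maintenance through collisions,
  and no posture/skeleton information beyond the box.
- The generator's detector noise is temporally independent; real detector
  failures cluster (e.g. during molts or at low contrast).
- The tile dedup radius is a surrogate for what was historically a manual
  judgment; eggs laid in physical contact inside a tile overlap region
  would be under-counted by construction.
- Published headline accuracies of box-detection trackers depend on their
  specific image sets and cannot be reproduced from synthetic scenarios;
  the tests here validate the measurement machinery, not any detector.
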
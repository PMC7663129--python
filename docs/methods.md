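# Methods

This note records the models, conventions and numerical choices behind
`copmat`, in the order the pipeline applies them.

## Mat recordings

A recording is a time-ordered list of frames; each frame holds the active
cells `(row, col, pressure)` of a fixed grid. Defaults follow common
walkway hardware: 240 Hz sampling and 12.7 mm cell pitch. Cell indices are
0-based and physical coordinates are **cell centers**: cell (r, c) sits at
`a = (c + 0.5)·pitch`, `b = (r + 0.5)·pitch` (a = horizontal axis,
b = vertical/long axis; the long axis is the default direction of
progression, configurable per recording). Pressure may be graded or binary
(binary devices write 1.0); no calibration to Newtons is assumed, only
non-negativity, because every downstream quantity is a pressure-weighted
*centroid*. The interchange format is long-form CSV with a `#key=value`
header; empty frames are preserved as `frame,,,` rows and floats are
written in shortest round-trip form, so `read(write(x)) == x` exactly.

## Footfall segmentation

Each cell's active frames are split into intervals, bridging gaps of at
most `max_gap` frames (default 2 — a flickering sensor stays in its
footfall). Intervals are merged by union-find when their cells are
identical or 8-adjacent and their spans overlap or are within `max_gap`
frames. Clusters with fewer than `min_cells` cells (default 5) are
discarded as debris. Left/right labels come from the sign of the cross
product of the local progression direction (neighbour-to-neighbour
centroid vector) with each footfall's offset from the neighbour midpoint;
the first and last footfalls take the side opposite their neighbour, and a
two-footfall list falls back to the walking axis and mean centroid. If the
resulting sequence fails to alternate, all labels become `unknown` rather
than guessing.

## Foot axis, thirds and the foot frame

The thirds are measured along the foot axis, but the axis endpoints (heel
and toe centers) are centroids of the outer thirds — a circular
definition. It is resolved deterministically: a provisional axis (first
principal component of the cell centers, oriented along the walking
direction) defines initial thirds; H and T are the proximal/distal
centroids; one refinement pass recomputes the thirds along the H→T line
and re-derives H and T. The thirds cut the along-axis extent of the cell
centers into three equal intervals; boundary ties go to the more proximal
interval, with a 1e-9 relative tolerance so that exact symmetries (a
mirrored mat) classify boundary cells identically despite floating-point
rounding. "Pivot points" are area centroids of the outer-third cell sets.

θ_c = atan2(c − e, d − f) for T = (c, d), H = (e, f): this sign convention
guarantees the rotation maps T onto the positive y-axis. The rotation is a
rigid isometry; for left feet x is negated afterwards so +x is always
medial→lateral. Foot length and width are the extents of the cell centers
along/across the axis **plus one cell pitch**, since centers alone
underestimate the physical extent by half a cell on each side. Footfalls
with fewer than 3 cells or zero extent along the provisional axis are
rejected as degenerate.

## Stance events

Event times are taken at frame resolution — the device samples at 240 Hz
and no sub-frame interpolation is attempted. A cell's activation is its
first-on time and its deactivation its last-off time within the footfall.
The foot-flat criterion counts **distinct cells ever activated** with
threshold `ceil(0.78 · N)`; counting cells *concurrently* active instead
is available via `fft_rule="concurrent"` (the cumulative reading matches
"have been activated" and is the default). Footfalls whose six events come
out non-monotone are flagged invalid, excluded from parameter tables and
logged with the violated pair — the automated analogue of discarding
trials with unusual motions — never clamped into order. The five
subphases tile the stance exactly, so their normalised durations sum to
100% identically.

## COP parameters

The COP of a frame is the pressure-weighted centroid of the footfall's
active cell centers; frames with zero total pressure yield no sample.
Velocities use the **path-length** definition: Σ|Δx| (ML), Σ|Δy| (AP) or
Σ√(Δx²+Δy²) (total) over consecutive sample pairs, divided by the subphase
duration, in cm/s. A net-displacement variant sits behind
`velocity_mode="net"`; path length is the default because reported
anteroposterior velocities exceed what range/duration arithmetic can
produce. Interval membership is closed on both ends (with 1e-6 ms
floating-point slack); the step between two samples is attributed to the
subphase containing the **later** sample, so every step is counted exactly
once across the five exhaustive subphases. Empty subphases (coinciding
events) yield missing values, never zeros. Mean locations are signed
percentages of foot width (ML) and length (AP) — the COP legitimately
starts behind and medial of the heel center. Trajectory resampling
linearly interpolates x and y at 100 equally spaced stance percentages,
optionally normalised by foot dimensions for cohort-mean plots.

## Arch index

The arch index is the middle-third contact area of a toe-excluded
footprint over its total area, with thirds measured along the toe-excluded
footprint's own principal axis (hence rotation-invariant up to cell
discretisation). Without an explicit toe mask, the heuristic takes the
largest connected component as the sole, finds the most distal completely
empty cross-section row (the sole–toe gap) and removes components entirely
distal to it; if that would remove more than 40% of the area the geometry
is ambiguous and an explicit mask is required. Classification thresholds
default to the common convention (index < 0.21 high arch, > 0.26 low
arch) and are configurable.

## Reliability statistics

The design is subjects × k footfalls (complete-case: subjects missing any
of their first k values are dropped per parameter, because the
unreplicated two-way ANOVA needs a full matrix). From the mean squares
MSR (subjects), MSC (footfalls), MSE (residual):

- ICC(2,1) = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n), with the
  F-based absolute-agreement confidence interval (verified in tests
  against `pingouin.intraclass_corr`, which is used only as an oracle).
- ICC(2,k) = (MSR − MSE)/(MSR + (MSC − MSE)/n), algebraically identical to
  the Spearman–Brown prophecy of ICC(2,1) — a property the test suite
  asserts to 1e-12.
- The between-footfall F = MSC/MSE tests systematic bias across footfall
  repetitions; the between-subject F = MSR/MSE tests ICC > 0.
- required_k = ceil(R_target(1−R)/(R(1−R_target))) whole footfalls; an ICC
  of exactly 1 needs one footfall, a non-positive ICC cannot be prophesied
  and reports missing.
- CV% is the mean over subjects of 100·SD_i/|mean_i| (a pooled variant is
  available); it is not applicable to the signed mean-location parameters.
- SEM = SD·√(1 − ICC(2,k)) with SD the standard deviation of **subject
  means** — the measurement error of the k-footfall average, which is the
  quantity a protocol reports — and MDC = SEM·√2·z with z = 1.64 (90%
  confidence; the √2 reflects the difference of two measurements).

`sample_size_icc` implements the Fisher-transform approximation
n = 2 + k(z_α+z_β)²/(2(k−1)(Z(ρ₁)−Z(ρ₀))²) with
Z(ρ) = ½ln[(1+(k−1)ρ)/(1−ρ)]. It is advisory: exact small-sample rounding
conventions differ between published implementations by a subject or two
(the 0.5 → 0.6, α = 0.05 one-tailed, 80% power, k = 16 design point gives
91 here).

The bundled normative table (`copmat.reference_values`) carries published
single-footfall and seven-footfall ICCs, SEMs and MDCs for every COP
parameter at two walking speeds in 90 healthy young adults; it is input
data for prophecy/required-footfall calculations and the scale reference
for the generator, not something this package computes.

## The synthetic generator

The generator emulates what it needs to and no more: its purpose is exact
ground truth for the pipeline, at the scale of real cohorts.

*Geometry.* A foot-shaped cell template (rounded heel, medially waisted
midfoot — waist depth 0.6 of the medial half-width — widest at the
metatarsal heads) is placed per step with alternating sides, subject-level
toe-out angle, and forward progression from walking speed and cadence
(defaults: foot 240.1 × 100.1 mm, speed 129 cm/s, cadence 118.3
steps/min, stance 613.7 ms).

*Contact wave.* A cell's activation time grows piecewise-linearly with its
along-foot position u, with knots at the configured event fractions
(defaults MON 8.83, FFT 40.85, HOT 59.32, MOF 87.02 % of stance);
deactivation likewise. The heel pad (u ≤ 0.10) strikes as one impact and
the toe pad (u ≥ 0.92) releases together — heel strike and push-off are
far faster than the stance, and without this the COP would briefly hang on
a single barely-loaded corner cell, which no real foot produces. Pressure
rises as a quarter-sine over at most 50 ms and falls as a quarter-cosine,
on top of a sensor activation threshold (0.15 of nominal): mat sensors
switch on at a load threshold, so reported pressure never hovers near
zero. A slow mediolateral weight sweep (−cos(2πτ) over stance, gain 0.35)
biases pressure medially at the ends of stance and laterally in midstance,
dragging the COP across the foot at timescales a 240 Hz device resolves.
At zero timing jitter all switch times sit on the device clock; the
`timing_jitter_ms` and `noise_rate` (flicker cells) parameters move them
off-grid and add debris.

*Ground truth.* Event times and the foot axis are computed by the
detector's own rules evaluated on the continuous planted cell times, so at
zero noise the pipeline must recover events exactly to the frame — and
does. Trajectory and parameter ground truth are evaluated on the device
clock grid (`oversample=1` by default): path-length velocities and max–min
ranges are defined on the sampled COP sequence, and a continuous path
length is strictly larger than any sampled one, so the sampled sequence is
the estimand; the continuous model remains accessible via larger
`oversample`. The planted placement (sides, positions, toe-out angle) is
independent truth: the axis estimate recovers a planted 30° toe-out within
3° and foot dimensions within one cell pitch.

*Variability.* Subject traits (foot size, stance, event fractions,
toe-out) are drawn from between-subject normals; per-footfall jitter adds
the within component. Within-subject event-fraction SDs were derived once
from the published single-footfall ICCs via σ_w = σ_b·√((1−R)/R). Event
fractions are clamped to preserve ordering with minimum gaps. Parameter
matrices for the ICC statistics come from the direct variance-components
model value(i,j) = μ + b_i + e_ij with true ICC σ_b²/(σ_b²+σ_w²).

*What passing tests do and do not show.* The generator matches real data
in scale and event structure, not in physiology: it has no double-support
force transfer between feet, no pathological patterns, no pressure
calibration, and its mediolateral COP dynamics are a smooth two-parameter
sweep rather than subtalar mechanics. Recovery tests therefore validate
the pipeline's geometry, event logic and arithmetic — not that any mat
measures gait well.

## Problem sizes and runtime

The test suite uses 4–16-step recordings, 1000-replicate Monte-Carlo runs
at the n = 90, k = 7 design point for estimator calibration, 300-replicate
bias checks and a 200-replicate CI-coverage check; the full suite runs in
well under a minute on one core. The acceptance script evaluates only
closed-form identities and runs in seconds.

## Known limitations

- Side assignment needs a roughly straight walk; turning paths defeat the
  running-midline logic and are labelled unknown.
- Partial footfalls at mat edges are not specially detected; they appear
  as small or degenerate clusters and are discarded or excluded.
- The concurrent foot-flat rule and net-displacement velocities are
  implemented but exercised less thoroughly than the defaults.
- The ICC confidence intervals assume the usual normal variance-components
  model; heavy-tailed parameters (velocities in short subphases) will show
  anti-conservative coverage.
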
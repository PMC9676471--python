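# Methods

## Problem setting

A UAV flies a straight pass over a row crop while a detector emits a
bounding box per visible plant per frame. Plants appear in dozens of
consecutive overlapping frames, so the counting problem is one of identity:
link detections of the same plant across frames and count each identity
once. `maizetrack` implements the tracking-by-detection approach — a
per-plant constant-velocity Kalman filter, IoU-gated optimal assignment,
lifecycle thresholds, and cross-line counting — together with a simulator
that reproduces the statistical structure this pipeline assumes.

## State estimation

Each track's state is t = (u, v, s, r, u̇, v̇, ṡ): box center, area,
aspect ratio, and per-frame rates for all but the aspect ratio. The model
is justified by the acquisition geometry: at high frame rate a uniformly
translating camera produces near-constant apparent velocity, and a nadir
view keeps plant scale (and hence box area) changing slowly.

The filter matrices (all overridable through `NoiseModel`):

| matrix | default | meaning |
|---|---|---|
| F | I₇ with F[0,4] = F[1,5] = F[2,6] = 1 | constant velocity, dt = 1 frame |
| Q | diag(1, 1, 1, 1, 10⁻², 10⁻², 10⁻⁴) | process noise; velocities trusted ~100× more than positions |
| H | [I₄ \| 0₄ₓ₃] | detections observe (u, v, s, r) directly |
| R | diag(1, 1, 10, 10) | detector area/aspect noisier than centers |
| P₀ | diag(10, 10, 10, 10, 10⁴, 10⁴, 10⁴) | new-track covariance; velocities start at 0 with large uncertainty |

P₀ is this package's choice (the filter family's standard practice of
starting unobserved velocities with large variance); the observation
blocks decouple, so the u-marginal of the 7-state filter is checked in the
tests against an independently coded 2-state filter, to which it agrees to
machine precision.

Numerical choices: the update uses the Joseph covariance form
(I−KH)P(I−KH)ᵀ + KRKᵀ, which preserves symmetry and positive
semi-definiteness under rounding (verified to an eigenvalue floor of
−10⁻⁸ over 1000 random cycles); the gain solves the S-system rather than
inverting S; covariances are re-symmetrized after every step. If a
predicted area would be non-positive (s + ṡ ≤ 0) the area rate is clamped
to zero for that prediction, keeping the emitted box valid without killing
the track.

## Association

The frame's cost matrix is C[i,j] = IoU(predicted trackᵢ, detectionⱼ).
`scipy.optimize.linear_sum_assignment` maximizes total IoU over one-to-one
assignments (equivalent to minimizing Σ(1 − IoU) at fixed cardinality);
assigned pairs with IoU < T_thresh = 0.3 are then demoted to unmatched on
both sides. Gating after solving is the default because the two-step
description of the method is solve-then-threshold; the alternative order
(zero sub-threshold entries first) is exposed as
`TrackerConfig.gate_before_solve` since the two can differ in rare
configurations. Ties between equal-total assignments are resolved by
whatever the deterministic solver returns; no contract depends on tie
order. Boxes that merely share an edge have IoU 0 and can never match.

## Lifecycle and counting

Per frame: predict all tracks → associate → update matched tracks
(hits + 1, v_lost = 0) → unmatched tracks get v_lost + 1 → remove tracks
with v_lost ≥ T_lost → spawn a new track per unmatched detection. New
tracks are initialized (velocities 0), not updated, in their birth frame
and join association the next frame. Track ids increase strictly and are
never reused.

T_lost = 5 and T_life = 3 are this package's defaults: the mechanism
requires the thresholds but no canonical values exist, and these suit
~30 FPS footage where a detector dropout rarely exceeds a few frames.
"Cumulative existences" for count eligibility is interpreted as
matched-frame count (hits), not age, because hits is the statistic that
separates sporadic false positives from real plants; `life_on_age`
switches to the age interpretation.

The counting baseline sits at `baseline_fraction` × image height (default
½, where tracking is most reliable — plants near the frame edges suffer
perspective distortion and detector instability). A crossing is a strict
sign change of (v − baseline) between consecutive frames of one track,
evaluated on the *filtered* center so a coasting track can cross during a
miss gap. Each track is counted at most once; eligibility requires
hits ≥ T_life at the moment of crossing (a crossing that happens earlier
is deliberately not counted retroactively). Both crossing directions count
by default — recording direction either way — and `direction=down|up`
restricts to one for constant-heading passes. A track that lands exactly
on the line is judged against its last strictly-off-line position, so
touching the line and retreating never counts, and a track that ends on
the line is not counted.

Consequences worth knowing: a track removed in the same frame it would
have crossed is not counted, and appending empty frames to a clip can in
principle add counts from tracks still coasting within T_lost frames of
the line — in a normal pass all crossings complete well before the clip
ends, and the tests exercise exactly that regime.

## The simulator

`SimConfig` describes a camera scrolling vertically over rows of plants
(rows run across the image; plants enter at the top and exit at the
bottom, so trajectories cross the horizontal baseline). Plants are laid
out on a jittered grid — `plant_spacing` (default 110 px) within rows,
`row_spacing` (default 90 px) between rows, ~6% positional scatter —
starting just above the first frame's view, so every plant is visible for
many frames (≈ 67 at the defaults) before reaching the line. Per-plant box
sizes are drawn once from N(42, 4²) px, floored at 8 px. Default geometry
is a 960×540 frame at 4 px/frame; `n_frames ≤ 0` auto-sizes the clip so
the deepest plant clears the line with a 10-frame margin.

Noise, applied per frame: each visible plant's box is dropped with
probability `p_miss`; Poisson(`fp_rate`) spurious boxes appear uniformly
in the image, living `fp_persist_frames` frames (1 by default; longer
values emulate weed-like clutter that scrolls with the field and stresses
the T_life gate); surviving centers get N(0, `jitter_sd`²) noise and sizes
a matching log-normal factor (σ = jitter_sd / box_size_mean). One seeded
`numpy` generator drives everything, so clips are pure functions of their
configuration.

`GroundTruth.true_count` — the number of plants whose true center
trajectory crosses the baseline within the clip — plays the role of a
manual count of the same pass. `evaluate_counts` reports the R² of the
ordinary least-squares fit of predicted on true counts, plus MAE and
signed bias.

What the simulator does *not* emulate: appearance (no imagery), detector
confidence structure, correlated misses from occlusion or blur, camera
vibration or heading drift, and plant-size growth within a pass. Passing
synthetic tests therefore validates the tracking/counting logic under the
model's own assumptions — uniform motion, independent misses — not
detector quality or robustness to motion that violates those assumptions.

## Validation conditions

The test suite and `scripts/acceptance.py` use desk-scale problem sizes
chosen to exercise every code path while keeping a full run in seconds:
500 random matrices (≤ 7×7) against brute-force assignment enumeration;
60-frame exact trajectories for the filter (error ≤ 10⁻³ px after a
10-frame burn-in); 50 noiseless clips of 5–40 plants for exact count
agreement; 20 clips at p_miss = 0.1, fp_rate = 0.2/frame, jitter 2 px for
noisy recovery (the simulation analogue of field regression studies —
under these conditions the pipeline recovers counts exactly, so R² = 1.0
and MAE = 0); the gap boundary at g = T_lost − 1 vs. g = T_lost; a
150-frame oscillating trajectory crossing the line 7 times (counted once);
300 frames of pure clutter at 1 FP/frame (counted zero); and 200 integer
boxes against a pixel-membership IoU oracle. Real-footage headline numbers
from field studies (e.g. R² ≈ 0.92 against manual counts) depend on the
original videos and detector weights and are out of scope here.
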
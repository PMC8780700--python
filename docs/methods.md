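# Methods

This note documents the models implemented in `headgest`, the synthetic
study conditions the package is validated under, and the numerical and
design choices made where more than one reasonable option existed.

## Problem setting

A user who would normally press a mechanical head switch performs
out-and-back "reaching" head movements in front of a webcam.  The system
must detect those functional movements — and reject everything else:
returns to rest, small adjustments, movements in other directions, and
involuntary motion (tremor, choreiform jerks) — because in a sweep-scanning
virtual keyboard every false positive selects a wrong item and is expensive
to undo.  The pipeline is therefore evaluated primarily by ROC behaviour,
with emphasis on the low-false-positive regime.

## Tracking front-end

**Detection and normalization.**  The face detector is pluggable: any
callable mapping an image to candidate rectangles works, and a
`reference_rect` config bypasses detection entirely.  The built-in detector
thresholds skin-tone hues in HSV and returns connected-component bounding
boxes; among candidates only the largest rectangle is kept (the user is
assumed closest to the camera).  The first frame fixes a crop-and-scale
transform: a square window of side `3·w_h0` centred on the face, resized to
a canonical 300 px ROI.  The same transform is applied to every later
frame, which makes trajectories comparable across sessions regardless of
face size and camera distance.

**Mean shift.**  The target model is a 16×8 hue×saturation histogram taken
from the face rectangle shrunk by 20% (removing most hair pixels); the
value channel is ignored for lighting robustness.  Pixel weights use a
posterior-probability-style ratio `h_t(b) / (h_t(b) + h_bg(b))` between
target and background histogram mass (the background histogram comes from
the ROI outside the target); plain back-projection is available as an
alternative strategy.  The search region is 50% larger than the *unshrunk*
scaled face rectangle.  This matters: the centroid window during iteration
is search-sized, because a window smaller than the colour blob sits on a
flat weight plateau and stalls, lagging fast movements by many pixels.
The tracked point (a weight centroid) sits at a constant offset from the
geometric face centre — hair exclusion and interior features are not
symmetric — so `track_video` measures that offset once on the reference
frame (iterating the tracker to its fixed point on a static face) and
subtracts it.

**Kalman filter.**  A constant-velocity model over state (x, y, ẋ, ẏ) with
white-acceleration process noise σ_a and isotropic measurement noise σ_m.
The filter's velocity state is the source of the downstream speed
magnitude.  Covariances were selected by simulation, trading velocity noise
at rest against lag during reaches:

* video tracking default: σ_a = 3000 px/s², σ_m = 2 px.  Reach
  accelerations at ROI scale are a few thousand px/s²; a much smaller σ_a
  (e.g. 50) lags the head by tens of pixels and is unusable, while with
  3000 the rendered-video tracking error is ≈0.35 px RMS.
* synthetic-session smoothing default: σ_a = 30 px/s² with σ_m matched to
  the 0.5 px generator jitter.  This keeps the rest-state speed noise below
  the 2 px/s valley threshold (so segments open and close crisply) while
  reach speed bumps, though attenuated, remain an order of magnitude above
  the 8 px/s peak threshold.  Both are configurable.
* the initial velocity prior has std 3 px/s: tracking starts from a rest
  posture, and a loose prior lets the first seconds of measurement noise
  masquerade as movement (spurious startup segments).

## Segmentation

The speed magnitude ε = √(ẋ² + ẏ²) is cut by a finite-state machine
implementing a zero-velocity-crossing rule with hysteresis, since filtered
speed never reaches exactly zero: a segment opens at the last sample with
ε ≤ 2 px/s before ε exceeds 8 px/s, peaks at the argmax, and closes at the
first sample back at or below 2 px/s.  Episodes still open at the end of
the series are dropped; segments shorter than 5 samples (at 30 Hz) are
noise and discarded.  Adjacent segments may share exactly their boundary
valley sample.

An out-and-back reach has a bell-shaped speed profile *per half*, with a
momentary near-zero dip at peak displacement, so it can segment as two
bumps.  `merge_return` (default on) merges consecutive segments separated
by less than 0.3 s of rest, making the unit of classification the full
reach.  Both behaviours are available; the merge gap is far below the
1.5–2.5 s rest between scheduled movements, so distinct movements never
merge under the default conditions.

## Threshold classifier

Calibration takes the extremum of x (relative to the rest position x_h0)
per calibration movement, requires all extrema to lie on one side, and sets
x_t = mean extremum − direction·20 px.  The per-segment score is the signed
excursion `direction·(extremal x − x_h0)`, which is the quantity swept for
ROC curves; the streaming detector fires at the first crossing of x_t and
re-arms only after return within the threshold, so jitter at the boundary
cannot double-fire.  In cross-validation under heavy involuntary motion,
merged "valid" segments can extend to both sides of the reference; the fold
trainer then calibrates on the dominant-direction majority rather than
failing (the strict mixed-direction error remains in `calibrate_threshold`
for direct use).

## HMM classifier

A reach is modelled as a sequence of stages: a 4-state HMM, left-to-right
with self-transitions (last state absorbing) by default since the stages of
a reach are ordered; a fully ergodic topology is available.  Emissions are
full-covariance Gaussians over P (reference-relative position, px),
V (velocity, px/s) or PV features.  Training:

1. k-means (k = 4, 10 restarts, seeded) on the pooled observations of the
   valid training segments; each cluster's mean/covariance seeds a state.
   States are ordered by the clusters' mean relative time of occurrence
   within their segments, so "state 1" is the earliest movement phase.
2. Baum–Welch re-estimates A, π and (by default) the emissions, treating
   the k-means densities strictly as initial estimates; a
   `update_emissions=False` mode freezes them.  The E-step uses the scaled
   forward–backward recursions over right-padded, masked batches (the
   per-sample maximum of the emission log-densities is factored out, so
   nothing underflows); structural zeros of the initial transition matrix
   are preserved automatically by EM.  Convergence: tol 1e-4 on the total
   log-likelihood, max 200 iterations.  Emission covariances are floored
   (eigenvalues ≥ 1e-4) only when needed, so EM monotonicity holds to
   1e-6 in practice; if responsibilities starve a state the update keeps
   the previous parameters, and if the E-step statistics ever go
   non-finite EM stops at the last valid model with a warning.

Classification does not length-normalize the log-likelihood `l_s`; instead
the segment length enters the decision statistic directly,
ψ = [l_s, n_s]ᵀ.  A bivariate normal null (sample mean and covariance,
ridge-regularized if singular) is fitted on the valid training segments,
and a new segment's Mahalanobis distance d is tested against
χ²(2 df): valid iff d² ≤ the quantile at the configured confidence
(default 0.95).  The ROC score is −d, so all classifiers sweep in the same
direction.  Segments with fewer samples than states are rejected outright.

## Evaluation

Ground truth is the set of switch-activation times.  A segment is valid iff
an activation falls within [start − 0.5 s, end + 0.5 s]; each activation
labels at most one segment (nearest peak, earlier segment on ties), and
unmatched activations are counted as misses.  ROC curves sweep all distinct
scores (sklearn's implementation); the trapezoidal AUC equals the
Mann–Whitney concordance, which the tests verify exactly.  Cross-validation
is stratified 3-fold over segments, seeded; per fold the classifier is
retrained on the training split's valid segments and scores the validation
split.  The reported dispersion is the sample standard deviation across
folds.

## Synthetic study conditions

The generator's defaults define the conditions every end-to-end result in
this package refers to:

| parameter | default | rationale |
|---|---|---|
| frame rate | 30 Hz | webcam rate |
| reach amplitude | 120 px (ROI units) | comfortable lateral head reach on a 300 px ROI |
| reach duration | 0.8 s out-and-back | brisk volitional movement; peak speed 1.875·A/T_half ≈ 560 px/s |
| kinematics | minimum jerk per half | canonical bell-shaped functional movement; yields the valley–peak–valley pattern segmentation assumes |
| switch event | at peak displacement | a head switch is pressed at the movement extremum |
| rest between movements | 1.5–2.5 s (uniform) | scanning-keyboard pacing; also lets filtered speed settle between movements |
| amplitude/duration jitter | 8% relative | human variability; makes the −20 px calibration margin meaningful |
| measurement jitter | 0.5 px | mean-shift tracking noise at ROI scale |
| distractors | orthogonal / opposite / half-amplitude / slow-matched | the confusion modes a deployed system faces |
| tremor | sinusoid, 4 Hz, random fixed direction and phase | postural tremor approximation |
| choreiform | Poisson pulses at 0.5/s, heavy-tailed (t₃) magnitudes, 0.3 s pulses low-passed at 3 Hz | sustained choreiform activity; at much higher rates whole sessions merge into one segment and fold-wise evaluation becomes degenerate |

What the generator does **not** emulate: head rotation and perspective,
lighting changes, occlusions, correlated (non-white) tracking noise, trunk
motion, and any physiologically validated movement-disorder dynamics.
Passing results on synthetic sessions therefore demonstrate the internal
consistency of the pipeline and its comparative behaviour across classifier
designs — not clinical performance.  Rendered video uses a flat-shaded
elliptical head with hair cap and an interior feature band; it exercises
the full vision path but is far easier than real footage.

Tracking-accuracy measurements register the first-frame rest position
before comparing: the detector's rectangle centre and the renderer's
ellipse centre are different anatomical points, constant per session.
Rendered sessions use 80 px reaches so the head stays inside the
3-face-width ROI.

## Reported comparisons

With the defaults above, the acceptance script reproduces three qualitative
findings: (1) on clean sessions with orthogonal distractors all classifiers
are near-perfect; (2) when distractors match the reach amplitude but not
its velocity profile, HMM-V/PV retain AUC ≈ 1 while the threshold falls to
≈ 0.7 — the velocity structure is the information a position threshold
cannot see; (3) choreiform motion at reach amplitude degrades *every*
method (threshold ≈ 0.87–0.94, HMMs ≈ 0.4–0.6), chiefly because
segmentation fragments or merges movements, starving the HMM of clean
training segments — the same failure mode that limits deployment for users
with severe involuntary movements.

## Known limitations

* The mean-shift implementation tracks a single target and assumes the
  head's colour signature is stable; it has no re-detection after loss.
* The left-to-right HMM fixes 4 states; model-order selection is out of
  scope (the state count is configurable as plumbing only).
* Involuntary movement is treated purely as a disturbance; modelling it
  explicitly (e.g., with its own HMM) is future work.
* The threshold classifier cannot adapt when the effective movement range
  drifts mid-session (e.g., posture shifts); no re-calibration is built in.
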
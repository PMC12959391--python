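# Methods

This note documents the models behind `straintwin`, the choices made where
the design was genuinely open, and what the synthetic experiments do and do
not demonstrate.

## Body model

The body is a kinematic tree of 13 joints (lower back LB at the pelvis as
root; spine LB→UB→T; collars and arms T→{LC,RC}→{LS,RS}→{LE,RE}; legs
LB→{LT,RT}→{LK,RK}), three intrinsic X→Y→Z Euler degrees of freedom per
joint, 39 in total. All public angles are degrees; coordinates are
right-handed, Y-up, meters. The hips attach to the pelvis *pre-rotation*
frame: lumbar (LB) rotation bends the trunk relative to the legs rather than
rotating the whole body rigidly. Global rigid motion is a separate optional
root transform, which keeps the rigid-equivariance property testable.

The skin is the smooth-minimum union of one capsule per bone, extracted by
marching cubes at a configurable voxel pitch (default 30 mm). A
signed-distance union was chosen over a boolean mesh union because it is
robust, dependency-free and directly yields the watertight, smoothly blended
single-component surface the geodesic solver needs; halving the pitch
roughly quadruples the face count without moving the skeleton.

Skinning weights fall off as a Gaussian of bone distance, where a bone's
distance is its capsule-surface distance **plus the axial overshoot** past
the segment ends. The overshoot term is essential: pure radial distance
grows only quadratically past a joint, which smears the weight transition
across half a limb and makes bending barely stretch the skin. With the
axial term the transition is confined to roughly ±`skin_blend_radius`
(default 5 cm) around the joint plane.

Known limitations: capsules are rotationally symmetric, so axial limb
rotations deform the skin only through the blend regions and are harder to
sense than on a real body; there is no soft-tissue dynamics, and the inner
side of a strongly flexed joint interpenetrates as linear blend skinning
always does.

## Movement ranges

Per-DoF movement ranges come from a 2000-bin histogram over [−180°, 180°]
(bin width 0.18°). Because the source analysis does not state how ranges
were "decided" from histograms, the range is the smallest contiguous bin
span holding a configurable fraction of the corpus mass (default 0.995;
coverage 1 gives the exact support). The default generator ranges are
physiological magnitudes adapted to the capsule body's axis conventions
(e.g. knees flex 0–130° about X; elbows flex about Y because the arms point
along ±X in the rest pose).

## Sensor placement

A sensor is a 160 mm strip fixed along a material line on the fabric. Its
candidate paths are traced over the rest mesh from a grid of center vertices
around each joint (default spacing 30 mm within a 120 mm geodesic radius,
seeded from the whole ring of vertices nearest the joint so the neighborhood
wraps the limb) in tangent directions every 15° (mod 180°), stepping 10 mm
and re-projecting onto the surface.

A candidate's score is the maximum relative change of its *posed path
length* over a 9-sample sweep of each of the joint's DoF ranges. The posed
length is the skinned polyline length of the fixed material path — a strip
sewn to fabric cannot re-route to the instantaneous shortest path, and this
also makes per-frame simulation tractable. Geodesic distances proper
(Dijkstra on the edge graph augmented with edge-midpoint subdivision,
checked against an independent Dijkstra oracle in the tests) are used for
the joint neighborhoods, the drift propagation field and diagnostics.

The suit designer ranks candidates by **elongation** (positive stretch
only). The capacitance model responds only to stretch — slack fabric
buckles — so a strip whose length only decreases during a sweep carries no
signal; ranking by absolute length change placed knee sensors on the
slackening side and produced a suit that could not sense knee flexion. The
`stretch_score` operation still offers the absolute mode. Selection is
greedy by descending score with a 10 mm path-proximity overlap rule
(automating a manual overlap check), three sensors per joint and two for
the neck, 38 in total; ties break by enumeration order so designs are
deterministic.

## Sensor signal model

Capacitance follows a linear gauge law

    C(s, t) = c_base · (1 + g · max(s, 0)) + c_trace + drift(channel, t) + ε

with defaults c_base = 100 pF (the measured base capacitance of the real
strip is ≈100.6 pF), gauge g = 1, parasitic trace offset c_trace = 5 pF and
ε ~ N(0, (0.05 pF)²) drawn from a per-channel generator spawned from one
master seed. Strain clamps at −0.05 (fabric buckles rather than
compresses). A linear gauge was chosen because the reference
characterization shows a monotone, low-hysteresis response but no published
curve; hysteresis is deliberately not modelled.

Sweat drift is additive and bounded: each channel's onset is delayed by its
geodesic distance from the nearest seed region (defaults: both armpits and
knees) divided by a propagation speed (3 mm/s), after a global onset time
(120 s); past onset the drift rises as `max_drift·(1 − exp(−t/τ))`
(defaults 10 pF, τ = 300 s). These magnitudes are configuration guesses —
the source experiments show the spatial pattern but not per-sensor
magnitudes.

Streams are sampled at 40 Hz by linear interpolation of the 100 Hz angle
stream; simulating at 80 Hz and decimating reproduces the 40 Hz stream
exactly in the zero-noise limit.

## Motion generators

All generators are seeded, emit 100 Hz degrees, respect the configured
ranges, and label 1-minute class segments. Design choices:

- **Single-joint sweeps**: 11 joints × 3 axes in the standard order
  (LE, LS, RE, RS, UB, LB, T, LT, RT, LK, RK), five sinusoidal sweeps per
  segment, 387 s / 38,700 frames total; non-target DoFs carry a ±2° smooth
  wander because a wearer cannot hold them perfectly still.
- **Multijoint routine**: a choreographed sequence of eight rhythmic
  exercises. Within an exercise every active DoF oscillates at the
  exercise's beat (or its first harmonic) with quantized phase, and the
  whole pose ramps through the neutral stance between exercises — a
  scripted warm-up routine is periodic and synergistic, not 39 independent
  oscillators. Amplitudes are scaled so the mean summed angle-change rate
  (Σ|Δangle| per 10 ms over all DoFs) hits the target, default 15.9°/10 ms,
  after accounting for the stance transitions.
- **Pick-and-place**: one reach half-cycle per metronome beat (90 BPM at
  1.0×), so the reach frequency is 0.75·speed Hz; shoulder-dominant
  amplitudes for upper reaches, elbow-dominant for middle, elbows slightly
  above shoulders for lower.
- **Gait**: antiphase hip/knee sinusoids; cadence scales with the speed
  multiplier (0.9 Hz at 1.0×); step-width classes redistribute hip
  ab/adduction amplitude (2° to 22°); inclines raise hip flexion amplitude
  and offset and reduce knee amplitude (±0.8°, ±1.2°, ±0.6° per degree of
  slope), declines the reverse.
- **Session offsets**: every labeled class receives a random baseline
  posture offset (sd 3°, seeded). Each class in the reference protocols was
  its own recording, and re-donning a garment shifts the stationary pose
  offset — the frequency analyses of the real system explicitly remove such
  per-recording offsets. This is also what makes the three nominally
  identical baseline gait conditions (1.0×, regular width, 0° slope, which
  appear once in each of the speed/width/slope groups, 15 labels in total)
  distinguishable, as they were in the real study.
- **Sync squats**: five 2 s knee/hip flexion cycles prepended and appended.

The synthetic multijoint routine is *more* learnable than real calisthenics
(its pose manifold is exactly periodic), so the multijoint calibration error
here lands below the single-joint error rather than at the twofold ratio
seen on human data; the acceptance bound for it is an upper bound, not a
reproduction of that ratio.

## Preprocessing

Sensor streams are linearly interpolated to 100 Hz. Reference angles can be
filtered with a zero-phase 4th-order Butterworth low-pass at 10 Hz
(zero-phase avoids lag against labels; the synthetic reference is clean, so
the pipelines skip it by default). Clock alignment automates visual squat
matching: a coarse offset from full-stream FFT cross-correlation of the
knee-band signals, then per-end windowed cross-correlation around the first
and last squat trains with parabolic sub-frame interpolation, yielding the
offset and a linear clock scale. Injected offsets are recovered to well
under one 100 Hz frame; a 0.1% clock-rate mismatch is recovered to ~1e-4
relative. After synchronization the dataset is cropped to the protocol span:
the squat bursts are alignment artifacts, and the reference dataset sizes
(e.g. 38,700 samples for the 387 s protocol) count exactly the protocol.

Splits are 3:1:1. Calibration uses seeded frame-level random splits.
Classification uses *per-class* sequential splits (first 60% of each class's
timeline to train, then 20%/20%), since per-class sample counts in the
reference study are each split 3:1:1 in time order; a global sequential
split would place entire classes outside the training set.

## Calibration model

`AngleRegressor.fit` trains a scikit-learn MLP (five hidden layers × 100
ReLU units) with Adam (lr 1e-3, ε 1e-4) on minibatches of 64 for 10,000
gradient steps, driven step-by-step through `partial_fit` so that
"iterations" means gradient steps and the snapshot with the best validation
MSE is retained. Channels are z-scored with train-split statistics (raw pF
scales would swamp the initialization); angles stay raw in degrees — scaling
the targets was tried and degrades the range-weighted accuracy balance.
Results objects expose `predict`, `evaluate` (per-DoF mean absolute error,
per-joint aggregates, overall DoF-weighted mean) and `summary`.

The Savitzky–Golay drift baseline uses window 18,000 frames (forced odd,
clipped to the stream), polynomial order 3 (order unstated in the source;
3 preserves constants and ramps), applied twice, edge mode `nearest`.
Whether the baseline is subtracted before training is exposed as a flag
(`subtract_baseline`); measured on the drift-injected twin, raw training is
already robust (the random-split MLP absorbs slow additive drift) while
baseline subtraction also removes motion envelope and degrades accuracy, so
the drift-robustness property is tested on the raw-training path.
For *quantifying* drift under activity the study module uses a rolling
minimum instead (window 45 s): the capacitive response to motion is
non-negative, so the rolling minimum over at least one exercise block strips
motion and leaves base + drift; the smoothing baseline tracks movement
content and is kept for visualization. A channel's onset estimate is the
first time its drift track rises 5% of the configured maximum drift above
its start.

## Pattern recognition

Spectra are magnitude rFFTs per labeled segment with the DC bin reported
separately as the stationary pose offset; rectangular windowing suffices
because segments are long relative to the motion periods, and a Parseval
identity is enforced in the tests. Look-back windows never span label,
split or recording-gap boundaries.

No deep-learning framework is assumed: the LSTM (three layers, hidden 50,
linear softmax head) is implemented in numpy with full backpropagation
through time and Adam (lr 1e-3, ε 1e-4), gradient-checked against finite
differences. Training runs 1000 minibatch steps of 64 with a
best-validation-loss snapshot. With the default one-step look-back the
classifier is effectively a per-frame reader of the 38-channel pose
signature; longer look-backs enable frequency-based discrimination and are
exercised in the tests.

## Problem sizes

The unit and acceptance tests run the full pipelines at the protocol scales
stated in their docstrings: calibration at the full 387 s single-joint and
240 s multijoint scales, gait classification at 60 s per class; the
acceptance script uses 180 s per gait class (three 1-minute recordings'
worth). The drift-robustness and sensing-network properties use a 120 s
routine and 2500 training steps, which is past the point where the compared
models' ordering is stable.

## What passing means

All signals are generated by the same forward model the calibrator inverts:
no soft tissue, garment slip, electrode aging or marker occlusion exists in
the twin. Passing therefore validates the *pipeline* — placement logic,
signal conditioning, synchronization, training recipes, evaluation — and the
internal consistency of the published procedure, not the hardware accuracy
of any physical garment.
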
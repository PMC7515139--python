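# Methods

This note records the scientific and numerical choices behind `affmotion`:
what each stage assumes, which parameters matter, what the synthetic
corpus does and does not emulate, and where the design was genuinely open.

## Data model

A recording is a `MotionSequence`: `T ≥ 2` frames of 25 named joints in
the standard Kinect-v2 numbering (SpineBase = 0 … ThumbRight = 24), parent
links forming a tree rooted at SpineBase.  Positions are meters in the
sensor frame (x left, y up, z forward); orientations are three angles in
degrees.  The sensor reports no orientation for the head, the six
hand-related joints, the knees and the feet; these are stored as NaN
("absent"), never zero, so every downstream consumer must choose an
explicit fill policy.  Timestamps are required and strictly increasing; a
source that provides only frame numbers is assumed to run at 30 fps, the
native sensor rate.

## Body-local projection

Per frame, every non-root joint becomes `R_root^T (p − p_root)`, and
non-root orientations are (by default) re-expressed relative to the root
rotation.  The root channel is replaced by its displacement and rotation
against the first frame, expressed in the first frame's root axes, so the
representation is invariant under rigid motions of the whole scene while
still carrying hops, squats, and backing-out drifts.

The three orientation angles have no canonical order in the data format;
we read them as intrinsic yaw (about v) – pitch (about u) – roll (about w)
and expose the order as an argument.  Any fixed convention preserves the
invariance properties; the choice only matters for interoperability with
other consumers of the same files.  Frames whose root orientation is
missing or non-finite fall back to the previous frame's rotation (identity
at the first frame) when explicitly allowed, favouring continuity over
failure.

## Keyframe extraction

Douglas–Peucker/Lowe curve simplification per joint trajectory: split
recursively at the point of maximum perpendicular (point-to-segment)
distance to the chord while that distance exceeds the error rate ε.  Ties
are broken toward the lowest index, which makes the binary split tree
independent of ε; ε only prunes it.  Two properties follow and are tested:
keyframe sets are *nested* across error rates, and counts are
non-increasing in ε.  Per-joint sets are merged by union over the 19
non-hand joints (a frame is key if it is salient for *any* joint);
per-joint output is available for inspection.

ε defaults to 0.03 m with 0.05 m as the supported alternative; 0.01–0.02 m
select nearly every frame (they sit at the sensor's noise scale) and
0.10–0.15 m retain little beyond the endpoints, so both extremes are
available but flagged.  Extraction runs on body-local coordinates, before
subject-scale division, so ε keeps its physical meaning in meters.

## Normalization

**Subject scale.** Each subject's joint vectors are divided by
`median ‖J20 − J0‖` (SpineBase–SpineShoulder distance) pooled over all
frames of that subject's neutral recordings.  These two joints have the
lowest positional noise, and using the neutral recordings (rather than the
recording being normalized) keeps whole-body vertical events in emotional
recordings visible in the root channel.  Orientations are angles and are
left untouched.  A subject with no neutral recordings is an error unless a
fallback scale is supplied.

**Padding and z-scoring.** Keyframed feature matrices are zero-padded to
the corpus maximum with a boolean mask (real rows form a prefix).  A
single mean/std per feature is then computed over the union of real rows
of all sequences; real rows are standardized, pad rows stay exactly zero.
Features whose pooled standard deviation is zero (up to a 1e-12 relative
tolerance — constant columns produce rounding-level std) are mapped to
zero with a warning; the orientation channels of joints without reported
orientation are constant by construction, so this path is routine, not
exceptional.  Whether the z-score is per-feature or one global scalar is
ambiguous in principle; per-feature is the default, the global variant is
available (`per_feature=False`).

Inside cross-validation the standardizer is fit on the training subjects
of each fold and applied to the test fold, preventing normalization
leakage; fitting once on the whole corpus reproduces the single-pass
variant.

## Feature sets

Six sets: {P, O, PO} × {full 19 non-hand joints, upper 11}.  Each is
3 channels per joint per family (6 for the combined sets) plus exactly one
shared temporal channel — the keyframe timestamp normalized to [0, 1] over
the recording — giving widths 58/58/115/34/34/67.  The published width
table over-determines this structure: with the six hand joints excluded,
`PO = P + O − 1` forces exactly one channel shared between the position
and orientation blocks, and a normalized time index is the semantically
plausible candidate (keyframes are irregularly spaced, so their timing is
informative).  The channel can be disabled, with a warning that widths
then drop to 57/114-style counts.  Hand joints are excluded everywhere:
their tracked motion is dominated by sensor error, and wrist position is
an adequate proxy for hand position.

## Quantity of motion

For joint j and emotion e, the mean over recordings of the mean
per-transition displacement of j *in its parent joint's local frame*
(position differenced against the parent, rotated by the parent's
orientation where reported; the root uses its first-frame displacement).
Normalizing by the number of transitions `F − 1` is the default; division
by the frame count `F` is available (`per_transition=False`) — for typical
100+-frame recordings the two differ by under 1%.  The statistic is
translation-invariant and non-negative; heatmaps are rendered with and
without the six hand-joint rows.

## Baseline features

A whole-recording scalar summary vector for classic (non-sequence)
classifiers: mean/max joint speed, mean/max second-difference acceleration,
a kinetic-energy proxy (mean summed squared speed), mean/max bounding-box
volume, a contraction index (mean wrist-to-SpineMid distance over trunk
length), density (mean distance to the frame centroid), mean jerk
magnitude, mean trunk pitch, and mean separations of symmetric joint pairs
plus wrist-to-head distance.  Exact finite-difference formulas are in the
`extract_baseline_features` docstring.  These definitions follow common
usage in affective-movement work; where the literature varies, the code's
formula is the contract.

## Classifiers and training protocol

Three architectures, implemented in numpy with hand-written
backpropagation (verified against central finite differences in the test
suite):

- **CNN** — the padded keyframes × features matrix as a one-channel image;
  3×3 convolutions, stride 1, each followed by 2×2 max pooling, reference
  channel widths 250/250/100, then a dense layer of 100 units.  Kernel and
  pooling geometry are the smallest standard choice for matrix-shaped
  input.  Pad rows are consumed as zeros.
- **Plain RNN** — tanh recurrences of 300/150/100 units with global
  gradient-norm clipping at 5 to survive exploding gradients.
- **RNN-LSTM** — 250/300/300 units, forget-gate bias initialized to 1.

All end in a dense softmax layer over 7, 6 (neutral dropped), or 4
(sadness/fear/anger/happiness) classes.  Recurrent models carry hidden
state through padded steps, so the final state always equals the state at
the last real keyframe and pad content cannot influence the output (tested
directly).  Training: Adam on cross-entropy, up to 500 epochs, early stop
after 30 epochs without training-loss improvement (minimum delta 1e-4; no
validation split is used for stopping).  Learning rate 1e-3 and batch size
32 are conventional defaults and configurable.  All randomness flows from
one integer seed; identical seeds give bit-identical weights.

**Cross-validation.** "Leave-one-subject-out with 10 folds" over 16
subjects cannot be literal, so the default protocol is subject-grouped
10-fold CV: subjects are shuffled and partitioned into folds (with 16
subjects, six folds of two and four of one), and no subject's recordings
appear on both sides of any split — asserted as a hard invariant at run
time.  Strict LOSO (`folds="loso"`) is available.  Reported accuracy is
sample-weighted within an iteration and averaged over iterations; whether
a fold-weighted mean was intended elsewhere is unknowable, and the two
differ only when fold sizes differ.

## Synthetic corpus

The generator emulates the corpus design the pipeline assumes: 16 subjects
(statures drawn from 1.55–1.95 m), 7 emotions, 5 repetitions, 3.5–5 s at
30 fps, 560 recordings in total.  Each subject is an articulated skeleton
with fixed bone offsets; an emotion archetype actuates shoulders, elbows,
wrists, spine, neck, hips and knees with smooth sinusoidal rotation
strokes (per-repetition amplitude/phase variation), plus root events — a
hop for happiness, crouch-and-retreat for fear, a slow backing-away for
disgust.  Forward kinematics keeps bone lengths exactly constant before
jitter; positional jitter is Gaussian with σ = 3 mm on body joints and
12 mm on hand joints.  Archetype tempos (0.25–1.6 Hz) were chosen so that
wrist speeds stay in the 0.5–2 m/s range of natural gesturing and curve
simplification at 3 cm retains a meaningful subset of frames.

Emitted orientations are sensor-style: the root rotation plus a slow
small-amplitude wobble per joint, not the exact kinematic frames.  Exact
frames would make every joint's parent-relative position constant and the
quantity-of-motion statistic degenerate; coarse orientation tracking also
matches what the real device provides.  Disgust and fear deliberately
share a "backing out, hands near the head" motif so that their mutual
confusion structure is a meaningful test target.

**What passing tests do and do not show.** The archetypes are
well-separated by construction — distinct tempos, amplitudes, and joint
involvement — so high cross-validated accuracy (99.6% for the 48-unit
LSTM on set P at ε = 0.03, subject-grouped 10-fold CV, one iteration)
demonstrates that the pipeline preserves and recovers class structure
end-to-end, not that real acted emotions are this separable: the
generator has no inter-subject style variation beyond stature and random
stroke phases, no expression ambiguity, and no tracking dropouts (those
are simulated separately by `degrade` for the quality-filter path).
Accuracies on real corpora are expected to be far lower.

## Problem sizes used in the checks

The acceptance suite runs the full 560-recording default corpus for the
corpus-design and label-recovery checks; the label-recovery check uses a
single-hidden-layer 48-unit LSTM, 20 epochs maximum, one CV iteration —
the reference 250/300/300 architecture and 10 iterations are supported by
configuration, and at this degree of class separation extra capacity and
repetitions do not change the conclusion.  Exactness checks (keyframe
oracle, quantity of motion, invariances) run on hundreds of random
trajectories and 20-recording corpora at tolerances of 1e-9/1e-12.
`scripts/acceptance.py` measures the six feature-set widths on a
2-subject × 7-emotion corpus; the widths are structural and independent of
corpus size.

## Known limitations

- Motion is kinematic and sinusoidal, not biomechanically simulated; no
  balance, ground contact, or momentum constraints.
- Euler-angle orientations are convention-dependent; gimbal-adjacent root
  orientations are handled by continuity fallback rather than quaternion
  re-estimation.
- The CNN consumes zero padding as signal-free rows rather than masking;
  with variable-length corpora this mildly favours the recurrent models.
- Native sensor files (XEF) and live capture are out of scope; ingestion
  is via the documented CSV/JSONL schema only.
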
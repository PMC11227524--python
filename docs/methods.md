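# Methods

This note records the models, conventions and design choices behind
`hjdpose`, in the order the pipeline applies them.

## Trajectory model and units

Recordings are uniform-rate trajectories of 12 named keypoints (Head,
CenterPelvis, L/R Hip, L/R Shoulder, L/R Hand, L/R Knee, L/R Foot), stored
in millimetres — the native convention of optical motion capture — at
100 Hz by default.  Frames are 0-based; the time of frame *i* is
`start_time + i / sample_rate`; stage annotations use half-open intervals
`[start, end)` so that every instant belongs to at most one stage and
windowing arithmetic has no boundary ambiguity.  NaN is the single
missing-value sentinel throughout.  Displacement rates are converted to
m/min only at reporting time.

## Cleaning

Spike removal and gap filling act independently on each (marker, axis)
scalar series:

- **Three-sigma rule.** The series mean `E` and *population* standard
  deviation σ (divide by N; the choice is arbitrary but fixed for
  reproducibility) are computed once over the valid samples of the whole
  recording — not re-estimated after removals — and samples strictly
  outside the inclusive band `[E − kσ, E + kσ]` (k = 3) become NaN.
  Inclusive bounds mean a constant series (σ = 0) is untouched.  Whether
  to compute the statistics per stage instead is exposed as future config;
  whole-recording is the default because a single fixed `E, σ` is the
  simplest consistent reading of the rule.
- **Cubic spline.** Interior NaN runs are filled with a not-a-knot cubic
  spline (scipy) through the valid samples — not-a-knot reproduces cubic
  polynomials exactly and needs no derivative guesses.  Leading/trailing
  gaps hold the nearest valid value instead of extrapolating, because
  extrapolated cubics diverge.  At least 4 anchors are required; a series
  with fewer (e.g. a marker absent for essentially the whole recording)
  raises an error naming the marker, mirroring the subject-exclusion rule
  such data would trigger in practice.

Cleaning one's own output is *not* a fixed point in general (removals
change `E` and σ), but on generator data a second pass touches well under
1% of samples; the test suite asserts that bound.

## HJD descriptors

The body frame at each frame is built entirely from markers: `e_lat` is
the unit LHip→RHip vector; `e_long` is the Head−CenterPelvis direction
orthogonalized against `e_lat`; `e_up = e_lat × e_long`.  Because no
external (gravity or lab) axis enters, descriptors are *exactly*
equivariant: a rigid motion of all markers rotates the frame with the
body and leaves every body-frame displacement coordinate unchanged up to
floating-point error (the suite bounds the HJD change by 1e−9).

Directions are binned on an equal-angle grid: azimuth `α ∈ [−π, π)`
measured from `e_lat` in the lateral–longitudinal plane (n_az = 8
sectors), elevation `θ ∈ [−π/2, π/2]` toward `e_up` (n_el = 8 bands, the
closed top edge clamped into the last band), bin index
`el_idx·n_az + az_idx`, 64 bins total.  The 8×8 factorization of 64 and
the discarding of the radial coordinate are design choices — the
descriptor is an occupancy of *directions* — and both are configurable.
A zero displacement (joint coincident with the root) has no direction; it
inherits the previous frame's bin (bin 0 at the start), a rule that only
matters for degenerate inputs but keeps the map total.

An HJD is the per-bin fraction of window frames (entries sum to 1), so
windows with different frame counts are comparable.  Fused features
concatenate (1D) or stack (2D) per-joint HJDs in a fixed order —
LHand, RHand | LKnee, RKnee | LFoot, RFoot — and permutations are
rejected rather than silently reordered.

Sliding windows are 5 s wide with a 4 s stride for training (5 s windows
with 1 s overlap); temporal-analysis curves use the same width at a fine
stride (down to one frame).  The stride grid restarts at each annotated
stage boundary, so a stage of length L yields exactly
`floor((L − 5)/4) + 1` labelled windows and no window ever straddles a
boundary; spans outside the annotation yield unlabelled windows.

## Classifiers

All seven classifiers are scikit-learn estimators over the flattened
feature vector (2D models receive `n_joints` and reshape internally).

- **kNN** (Euclidean, majority vote, ties to the lowest label): k = 5 by
  default; `n_neighbors="cv"` selects k from {1, 3, 5, 7, 9} by stratified
  cross-validation inside the training set.
- **LDA**: SVD solver; optional shrinkage (`lsqr`) for singular
  within-class scatter.
- **Neural models** run on the package's NumPy reverse-mode autodiff
  engine (gradients verified against central differences).  Shared
  training defaults: Adam, learning rate 1e−3, batch 32, seeded
  initialisation and shuffling, so runs are bit-reproducible on CPU.
  Epochs default to 100; the evaluation harness and acceptance runs use
  10–15 epochs, which suffices at these training-set sizes.
  - *FCNet*: dense 128→64→classes with ReLU.
  - *1D/2D Conv*: two conv layers (32 then 64 filters, kernel 3, stride 1,
    valid padding) each followed by max pooling, then a 64-unit dense
    layer.  Kernel heights adapt to the short joint axis of 2D inputs.
  - *1D/2D CapsNet*: the same conv stem *without pooling* — aggregation is
    delegated to dynamic routing — followed by a strided primary-capsule
    convolution (8 capsule channels × capsule dim 8; stride 4 in 1D, 3 in
    2D, chosen to keep the capsule count, and hence desk-scale training
    cost, moderate), a per-capsule linear prediction into
    `n_classes` 16-dimensional class capsules, and 3 routing iterations.
    Class scores are capsule norms; the loss is the margin loss with
    m₊ = 0.9, m₋ = 0.1, λ = 0.5 and no reconstruction decoder.  Routing
    logits start at zero; couplings are a softmax over parents; parents
    are squashed coupling-weighted sums; logits grow by the
    prediction–parent scalar product.  Backpropagation goes *through* the
    unrolled routing iterations.
- 2D architectures require ≥ 2 joints; single-joint feature sets are only
  valid for the 1D/classic models.

## Evaluation protocol

Leave-one-subject-out: one fold per subject, training on the rest.  Per
fold, the balance target is the minimum stage duration among *training*
subjects floored to whole seconds; each training (subject, stage) cell is
uniformly downsampled (seeded) to the window count that fits in that many
seconds, making the label histogram exactly flat.  All of the held-out
subject's labelled windows are scored; fold accuracy is percent correct,
and the report carries per-fold accuracies, their mean and standard
deviation (the sd is across folds, and labelled as such), pooled
confusion matrices, and one-way ANOVA (`F(df1, df2)`, p) for method
comparison.  One master seed fans out (via `SeedSequence`) to per-fold
sub-seeds for balancing and model initialisation.

The chance-level anchor for the balanced five-stage problem is
100/5 = 20%, checked in closed form and by Monte-Carlo.

## Synthetic cohort generator

Real infant recordings are request-only, so the generator exists to make
every pipeline stage testable and to realize the qualitative structure the
analysis assumes.  Each joint follows a sinusoidal mean path around a
supine rest posture (per-body-axis amplitude and frequency, random phase
per subject) with an Ornstein–Uhlenbeck process (stationary sd `amp_mm`,
mean-reversion 1.5 s⁻¹) riding on top as motor noise, and a two-state
Markov freeze gate that halts the joint.  Stage identity modulates these
parameters for the limbs; trunk markers stay quiet so the body frame is
stable.  The trigger-foot signatures: broad slow wander (B1), a
near-stationary foot with freeze bouts (B2), large lateral sweeps with
freeze/move alternation (CR1), a raised foot pumping along the
body-vertical axis (CR2), and the broadest, most vigorous wander (DC).
Path amplitudes are sized so the foot sweeps realistic direction-bin
ranges (single bins when frozen, ~10 bins when exploring), and OU
amplitudes so per-stage displacement rates order as
B2 < CR2/CR1 < B1 < DC.  Hands are weakly stage-modulated, knees
intermediately (they co-move with the legs), so feet-derived features
carry most of the class signal — the structural hypothesis the pipeline
is designed to detect.

A single `separation` knob δ ∈ [0, 1] linearly interpolates every
stage-profile parameter between the B1 baseline (δ = 0: all stages share
one movement law, no class signal) and the full stage signatures (δ = 1).
Subjects are rigidly re-posed (random yaw and translation) in the capture
volume, exercising view invariance end to end.  Measurement jitter
(0.5 mm sd), spike outliers and geometric-length occlusion gaps can be
layered on, with the ground-truth artifact mask returned for testing the
cleaner.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: biomechanical joint-chain constraints, soft
tissue and marker wobble, infant-specific rate/topology idiosyncrasies,
true nonstationary discovery dynamics within a stage, and any coupling
between infant and mobile.  Results on this generator validate the
*pipeline*, not developmental claims.

## Problem sizes

The test and acceptance runs use scaled cohorts chosen as a sensible
desk-scale default: 5 subjects; stage durations 45/45/30/45/45 s for
separability and temporal analyses (→ 51 labelled windows per subject,
140-window balanced training sets per fold), 30 s per stage for the null
cohort; 10–15 training epochs; 3 cohort seeds for the separability grid.
The full-length defaults (120/120/60/120/120 s) remain the generator's
nominal stage plan.

## Known limitations

- The azimuth×elevation factorization of the 64 bins, the discarded
  radial coordinate, and the hip-based lateral axis are fixed
  conventions; alternatives are config switches, not validated variants.
- The autodiff engine is deliberately minimal (float64, single-threaded);
  it is adequate for these feature sizes but not a general deep-learning
  stack, and CapsNet training dominates the pipeline's runtime.
- kNN/LDA hyperparameters beyond k and shrinkage (metrics, priors) are
  not searched.
- ANOVA is reported without sphericity correction.
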
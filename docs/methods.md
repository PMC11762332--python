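# Methods

This note records the models behind `drivecog`, the assumptions they
make, the parameters that matter, and the choices taken where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The measurement model

A driving session is a pair of multirate streams from one subject on a
standardized closed circuit: accelerometer and gyroscope at a nominal
10 Hz, GPS position and speed at 1 Hz. Turns appear as lobes in the
Z-axis gyroscope channel (yaw rate ω, rad/s); the analysis chain treats
that channel, synchronized GPS speed, and time as the only inputs —
accelerometer channels are simulated for format completeness but feed no
downstream feature, since the 26-feature schema uses gyroscope and GPS
quantities only.

Sign convention: left turn = positive yaw (right-handed axes, Z up),
configurable in `DetectionParams.left_positive` for sensor mounts with
the opposite orientation. Timestamps are seconds from session start.

## Circuit and session simulation

The default circuit is a 540 m lap driven 10 laps: two U-turns (nominal
radius 8 m), two left and two right 90° turns (nominal radius 10 m),
with six equal straights padding the lap. Heading closure is exact by
construction: the signed turn angles sum to +2π per lap (both U-turns
leftward).

Turn kinematics are driven by the subject profile rather than the
nominal radii — profile turn speed and peak yaw-rate, plus the circuit's
turn angles, fully determine each maneuver, and the three quantities
(speed, yaw-rate, radius) cannot be fixed independently. Each turn is a
trapezoidal yaw-rate lobe: linear ramps (1.5 s) into and out of a
plateau, with the plateau level re-solved after snapping phase durations
to the 0.1 s sample grid so that the integrated heading change equals
the designed turn angle *exactly*. Straight segments carry zero yaw;
their cruise time is sized so that each lap's path length equals the lap
length exactly, with speed ramps and a 1.2 s constant-speed margin
around every turn so GPS interpolation inside a turn window is never
contaminated by straight-line speeds. Positions are dead-reckoned from
speed and heading and exported as WGS-84 degrees around a configurable
origin.

Default kinematic magnitudes (free parameters, chosen once as plausible
for a closed-course protocol in a passenger car):

| parameter | normal | aggressive | unit |
|---|---|---|---|
| turn speed | 4 | 7 | m/s |
| straight speed | 8 | 10 | m/s |
| peak yaw, 90° turn | 0.4 | 0.64 | rad/s |
| peak yaw, U-turn | 0.6 | 0.96 | rad/s |
| lap-to-lap jitter CV | 0.05 | 0.05 | — |

The aggressive condition multiplies normal peak yaw-rates by 1.6 and
raises speeds, emulating sharp turns and rapid acceleration. Aggressive
straight speed is kept at 10 m/s so the lap still accommodates the
longer, faster turn paths with positive cruise time under jitter.

Sensor noise is additive Gaussian per channel: σ = 0.02 rad/s
(gyroscope), 0.05 m/s² (accelerometer), 0.2 m/s (GPS speed).

### Population structure and the impairment effect

Per-subject stable traits scale the base style: one *pace* factor
(CV 8%) applied to both speeds and yaw-rates — the circuit fixes turn
radii, so a driver who carries more speed through a turn must also yaw
faster — plus a small independent sharpness factor (CV 2%) on yaw-rate
only. Without between-subject variability every subject would share one
baseline and the classification task would be degenerate.

Impairment is a multiplicative shift scaled by a dimensionless
`effect_size`: MCI subjects' turn speeds and peak yaw-rates shrink by
15% × effect_size and their within-subject jitter CV grows by
30% × effect_size. `effect_size = 0` makes the status-conditional
distributions identical (verified by a seeded two-sample test at 100
subjects per class); the default is 1. The direction — slower, more
variable turning under impairment — is a modeling premise, and the
magnitudes are free parameters, not estimates.

Seeding: one master seed; per-(subject, condition) child seeds via
CRC-32 of `"seed:subject:condition"`, stable across platforms and kept
below 2³¹. Identical (config, seed) reproduce cohorts byte-for-byte.

### What the generator does not emulate

No vehicle dynamics (tire slip, suspension, load transfer), no braking
profiles, no GPS position error or multipath, no missing samples or
clock drift, no road traffic, and no within-session fatigue or learning.
Speed transitions are piecewise linear rather than physical. Passing
tests on this generator therefore demonstrates the *pipeline's*
correctness — detection, synchronization, leakage-free evaluation — and
the qualitative behavior of the effect model, not clinical validity on
real driving data.

## Turn detection and features

Peaks are found on |ω| after a centered moving-average smoothing
(0.5 s window) with a minimum height and prominence of 0.15 rad/s and a
minimum separation of 2 s. Smoothing stabilizes both peak location and
peak magnitude: the maximum of ~60 raw noisy samples inside a plateau
carries an upward extreme-value bias of roughly σ√(2 ln n), which the
average removes while leaving the plateau level intact (the default
plateau is several times wider than the smoothing window). Window
bounds sit where smoothed |ω| first falls below 10% of the peak, or at
the midpoint to an adjacent peak, whichever is tighter — windows never
overlap.

Classification uses the trapezoidal integral of ω over the window:
|angle| ≥ 135° → U-turn, 45°–135° → left/right 90° turn by sign,
below 45° → minor. The cuts are symmetric around 90° and 180°; minor
turns, and any maneuver nested inside a U-turn's window, are excluded
as steering adjustments rather than maneuvers.

Angular acceleration uses consecutive-sample differences,
α_k = (ω_{k+1} − ω_k)/Δt with Δt = 0.1 s; each turn contributes the
maximum and minimum of that sequence. The alternative reading — a
single difference across window endpoints — was rejected because it
yields one number per turn and cannot produce distinct α extrema.
A window needs at least two samples; single-sample windows are an error.

The per-subject feature vector has 26 slots in a fixed order: mean
|peak ω| for {left, right, U-turn} × {normal, aggressive} (6), mean
α_max and α_min for the same six combinations (12), mean GPS speed over
the turn window for the same six (6), and mean U-turn duration per
condition (2). Angular-velocity features are means of per-turn *peak*
magnitudes (the detection stage isolates each turn by its peak); a
per-sample in-turn mean would be an alternative reading. Combinations
with no observed turns are flagged missing, never zero-filled — a
subject lacking an aggressive session has exactly its 13
aggressive-condition slots missing.

## Evaluation

Folds partition *subjects*, stratified by status with test counts per
status differing by at most one across folds; with the default
21-subject roster and k = 4 the test folds hold 6/5/5/5 subjects with
exactly 2 MCI each. Inside each fold, and strictly on training
subjects: missing features are imputed with training means, features are
z-scored (zero-variance features clamp the scale to 1 with a warning),
and PCA retains 5 components by default (configurable, or the smallest
number reaching a variance threshold). Preprocessing fit per fold, not
globally, is the only reading consistent with an anti-leakage design;
the contribution stage's per-fold summation also presupposes it.

Classifier hyperparameters are fixed (no tuning): SVM C = 1, RBF,
gamma = scale; random forest with 100 gini trees; AdaBoost with 50
estimators at learning rate 1; k-NN with k = 5, Euclidean; QDA without
regularization; ridge-penalized logistic regression with C = 1, lbfgs,
100 iterations. Stochastic learners take the pipeline seed. Note QDA
estimates one covariance per class and needs more training subjects per
class than retained components; it is unusable on very small cohorts
and is omitted from the reduced demo configuration.

Metrics follow the standard confusion identities with MCI positive:
accuracy (TP+TN)/total, sensitivity TP/(TP+FN), specificity TN/(TN+FP),
PPV TP/(TP+FP), NPV TN/(TN+FN). A metric whose denominator is zero in a
fold is *undefined* — recorded as NaN, excluded from the across-fold
mean, with the number of contributing folds reported — never coerced to
zero. Means and stds are computed at full precision (population std
across contributing folds); display tables round to whole percent. The
per-class accuracy breakdown pools confusion counts across folds.

## Feature contributions

Per fold, score_j = Σᵢ |w_ij| γᵢ over the retained components, where
rows of W are the unit-norm component loadings and γ the
explained-variance ratios (ratios, not raw eigenvalues, so scores are
comparable across folds). Scores are summed element-wise across folds
and ranked descending, ties broken by feature index. Two invariants are
asserted on every fitted model: score_j ≤ Σγᵢ, and Σⱼ score_j ≤
√p · Σγᵢ (Cauchy–Schwarz with unit-norm rows). An optional normalized
variant (scores divided by their total) is exported alongside, clearly
labeled as a convenience.

## Numerical choices and degenerate inputs

- Phase durations snap to the 0.1 s grid; yaw plateaus and cruise speeds
  are re-solved after snapping so heading and lap length stay exact.
- GPS-to-gyro synchronization is piecewise-linear interpolation with
  edge clamping; it requires ≥ 2 GPS samples.
- Serialization uses 9 significant digits — round-trips are bit-stable
  at sensor noise scales.
- Quiet traces yield an empty event list, not an error; empty rosters
  are allowed with a warning when a status group is empty.
- Fold assignment refuses k larger than the subject count and warns when
  a status group has fewer than k members.
- All-constant training folds produce zero explained-variance ratios
  (not NaN) and majority-class predictions.

## Problem sizes in tests and the acceptance script

The test suite runs reduced problems chosen to exercise every code path
quickly: full-protocol single sessions (10 laps) for geometry and
recovery checks, 3-lap cohorts of 8–12 subjects for end-to-end runs, a
40-subject cohort (20/20) for the high-separation (effect_size = 2) and
zero-effect classification properties, and the full default 21-subject
protocol once. `scripts/acceptance.py` uses single full-protocol
sessions. These sizes are the package's choices for routine runs; all
scale up by configuration.

## Known limitations

- The 26-feature schema ignores accelerometer-derived and path-deviation
  behavior (lane keeping, braking), which real screening would likely
  include.
- The impairment model is a two-parameter caricature (mean shift +
  variance inflation); real MCI-related driving changes are
  heterogeneous across subjects and tasks.
- Chance-level behavior on zero-effect cohorts is assessed on the pooled
  across-model mean accuracy; individual flexible models on one fixed
  small cohort can drift beyond i.i.d.-binomial bounds by exploiting
  chance trait–label association — itself a useful reminder of why
  small-cohort results need subject-level cross-validation.
- U-turn duration is defined as the detection window's span (boundary at
  10% of peak), which systematically shortens the maneuver by a fraction
  of the ramp time; it is consistent across subjects and conditions.
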
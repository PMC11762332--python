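# drivecog

Turn-maneuver driving kinematics as a digital biomarker for mild
cognitive impairment (MCI).

Driving is a cognitively demanding task — turns in particular load
spatial orientation, divided attention and processing speed, abilities
that deteriorate early in cognitive decline. `drivecog` is a tested,
reusable pipeline for studying whether turning behavior recorded by an
in-vehicle sensor array (10 Hz accelerometer + gyroscope, 1 Hz GPS)
separates cognitively healthy older drivers from drivers with MCI. It is
aimed at researchers prototyping sensor-based cognitive screening who
need every stage — data generation, signal processing, evaluation — to
be deterministic, leakage-free and testable without access to clinical
recordings.

The package covers five stages, usable separately or as one chain:

1. **Synthetic cohorts** (`drivecog.synthetic`) — simulate standardized
   driving sessions on a closed 540 m circuit (two U-turns, two left and
   two right 90° turns, straights between) driven for 10 laps under a
   *normal* and an *aggressive* condition, with a controllable
   impairment effect (MCI subjects turn ~15% slower with ~30% more
   variability, scaled by `effect_size`).
2. **Sensor I/O** (`drivecog.sensor_io`) — CSV sensor logs and rosters,
   plus synchronization of 1 Hz GPS speed onto the 10 Hz gyro timeline
   by linear interpolation.
3. **Turn features** (`drivecog.turn_features`) — detect turning
   maneuvers as peaks in the Z-axis yaw rate ω, window each peak,
   classify by integrated heading change (90° turn / U-turn / minor),
   exclude minor adjustments, and compute per-turn kinematics including
   the angular acceleration α = dω/dt ≈ Δω/Δt from consecutive-sample
   differences. Per-subject means fill a fixed 26-feature vector:
   {mean |peak ω|, mean α_max, mean α_min, mean speed} ×
   {left, right, U-turn} × {normal, aggressive}, plus U-turn duration
   per condition.
4. **Leakage-free evaluation** (`drivecog.model_eval`) — 4-fold
   *inter-subject* cross-validation: each subject's data appear in
   exactly one test fold, and imputation, z-scaling and PCA (5 retained
   components) are fit on each fold's training subjects only. Six
   standard classifiers (SVM, random forest, AdaBoost, k-NN, QDA,
   logistic regression) with fixed textbook hyperparameters; accuracy,
   sensitivity, specificity, PPV and NPV reported as mean ± std across
   folds, with MCI as the positive class.
5. **Feature contributions** (`drivecog.contribution`) — rank the
   original 26 features by the variance-weighted absolute-loading score

   FeatureContribution_j = Σᵢ |w_ij| · γᵢ

   (loadings w of the retained principal components weighted by their
   explained-variance fractions γ), summed across folds.

A thin CLI (`drivecog simulate|extract|evaluate|contrib|report|run`)
wraps the library for shell use; `examples/` holds one short narrative
script per capability.

## Worked example

`examples/03_cross_validate_cohort.py` generates the default 21-subject
cohort (13 healthy, 8 MCI), extracts features and cross-validates:

```
model               accuracy  sensitivity  specificity
AdaBoost             81 ±  1%    75 ± 25%     85 ± 15%
KNN                  86 ±  8%    88 ± 22%     85 ± 15%
LogisticRegression   86 ±  8%    88 ± 22%     85 ± 15%
QDA                  73 ± 19%    50 ± 35%     88 ± 22%
RandomForest         86 ±  8%    88 ± 22%     85 ± 15%
SVM                  81 ± 14%    75 ± 43%     85 ± 15%
```

Each row is one classifier's mean ± std over the four test folds.
Sensitivity is the fraction of MCI drivers correctly flagged,
specificity the fraction of healthy drivers correctly cleared; the
pattern of higher specificity than sensitivity reflects the small MCI
group (two per test fold) and the modest default effect size. These
numbers describe the synthetic cohort only — the generator's effect
size, not any clinical dataset, determines them.

`examples/04_rank_feature_contributions.py` then ranks features; on
synthetic cohorts the turn angular-velocity/speed family dominates the
top of the list, with U-turn durations close behind.

## Layout

```
src/drivecog/
  synthetic/        circuit geometry, subject profiles, session simulator, cohorts
  sensor_io.py      CSV formats, GPS-gyro synchronization
  turn_features.py  peak detection, turn classification, 26-feature vectors
  model_eval.py     stratified inter-subject CV, PCA, classifiers, metrics
  contribution.py   variance-weighted loading contributions
  pipeline.py       end-to-end orchestration and reporting
  cli.py            thin command-line surface
  data/             packaged pilot roster and published fold map
examples/           one runnable narrative script per capability
docs/methods.md     models, assumptions, parameter choices, limitations
```
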
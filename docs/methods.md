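# Methods

## The staging problem and the cascade

Consumer trackers emit a stage label per 30-s epoch (1 = deep, 2 = light,
3 = REM, 4 = wake) whose agreement with a medical reference is stage-uneven:
light sleep is labeled fairly well, wakefulness and deep sleep poorly. The
cascade treats the device label as a prior to be *selectively corrected*: a
level-I binary classifier predicts, per epoch, whether the device label is
wrong (label 1) or right (label 0); only flagged epochs are re-labeled by a
level-II four-class classifier. The output therefore differs from the device
stream exactly where level I fired — the selective-correction identity the
test suite asserts. Two failure modes trade off: a timid detector leaves
device errors in place (low correcting power, CP), an aggressive one breaks
epochs the device had right (high over-correcting rate, OR).

Both levels see the same 21 features per epoch: ten static per night (age,
sex, PSQI; TST, WASO, SE, and the wake/light/deep/REM ratios — computed from
the *device* stream, since reference labels do not exist at prediction
time), and eleven dynamic (epoch index; device stage at offsets −3…+3;
epoch-mean heart rate and its first differences against the preceding and
succeeding epoch). Offsets that fall outside the night replicate the nearest
epoch's value, which keeps one feature row per epoch so evaluation covers
the whole night; the replicated heart-rate difference at the first/last
epoch is consequently 0.

## Classifiers, grids and resampling

Level I: gaussian naive Bayes, random forest, or linear-kernel SVM; the SVM
is the only learner whose features are z-scored (with training-partition
statistics, inside its pipeline). The decision rule is the estimator's
argmax (0.5 threshold for probabilistic outputs). Level II and the one-level
baselines: XGBoost. Default grids — NB var_smoothing {1e-9, 1e-6}; RF trees
{100, 500} × features-per-split {√M, M/3}; SVM C {0.01, 0.1, 1, 10}; XGBoost
depth {3, 6, 9} × learning rate {0.05, 0.1, 0.3} × rounds {50, 100, 200}.
`REDUCED_GRIDS` provides singleton grids for quick deterministic runs.
Inner-CV scoring is overall accuracy at level I and Cohen's Kappa at level
II (Kappa guards the imbalanced four-class objective); ties break to the
earlier grid point.

Random up sampling draws each class with replacement up to the majority
count (classes already at the target are kept as-is); down sampling draws
without replacement down to the minority count. Both produce *exact* class
balance for determinism, and every resampled row is an exact copy of an
original row — no interpolation. Resampling is applied to training
partitions only, including inside each inner tuning fold; evaluation folds
and held-out subjects are never resampled. The resampling knob is also
exposed at level I (default off).

## Evaluation protocol

Nested leave-one-subject-out CV: each subject's whole night is the test set
once; the remaining subjects are merged for training and inner 10-fold
stratified grid search (stratification keeps the small minority classes in
every fold; the fold count is clamped to the minimum class count when
necessary). Per split, level-I fits are shared across models with the same
algorithm, and the four-class XGBoost fit is shared between the one-level
baseline and the level-II re-classifiers with the same resampling strategy —
their training task is identical, so this is a pure cache, not an
approximation.

Microscopic measures per held-out subject: accuracy, Kappa (with the
p_e = 1 ⇒ 1 guard), MMCC (sklearn's multiclass Matthews R_K;
cross-checked in the tests against an independent contingency-table
implementation), the confusion matrix normalized within each ground-truth
column (the layout in which each truth stage's column sums to 100 %), CP and
OR. CP/OR are undefined when their stratum is empty (a device that never
errs, or never succeeds); they return NaN with a warning so degenerate
cohorts are flagged, not crashed on.

Macroscopic measures: per-stage total durations (0.5 min per epoch);
Bland–Altman differences oriented truth − model so a positive bias means the
model underestimates, LOA = bias ± 1.96 SD, a two-tailed one-sample t-test
of the bias, and a least-squares trend of differences on pair means. The
bias table e_ij (stage i × model j, in minutes, averaged across subjects)
feeds the MAB; a stage where all models tie (max = min) contributes 0 — all
models carry the same information there. Note the MAB is *relative to the
field of models in the report*: adding or removing models re-normalizes it.

Dataset characterization: Shannon diversity (natural log, so the maximum is
ln 4 at exact uniformity) of each test night's stage labels, and the
two-sample Anderson–Darling statistic (Scholz–Stephens k-sample form with
midrank tie correction, via scipy) between the pooled training labels and
the test labels, treating stage codes as ordinal. Pearson correlations
relate each per-subject metric to both statistics. The model-vs-baseline
t-tests in `summarize` are paired across subjects, matching the
within-subject design.

## The simulator

`simkit` emulates the study conditions rather than sleep physiology in
detail. Hypnograms are first-order Markov chains; the default transition
matrix is the sticky chain T = ρI + (1−ρ)·1π<sup>T</sup> with persistence
ρ = 0.85, whose stationary distribution is exactly π = the normalized
midpoints of the physiological proportion intervals (light 51.3 %, REM
20.5 %, deep 17.9 %, wake 10.3 %), giving stage bouts of a few minutes.
Device labels are drawn per epoch from a stage-conditional error matrix
whose default is a published consumer-tracker confusion pattern (light-truth
agreement 69.3 %, strong wake→light and deep↔light confusion; rows
renormalized to sum to 1, which absorbs a 4.4 % rounding deficit in the
deep-truth column of the source table). Heart rate is per-second gaussian
noise around per-stage means (defaults 56/62/68/74 bpm for
deep/light/REM/wake, SD 4 — a realistic but weakly informative signal),
with i.i.d. sample dropout (default 10 %) plus optional contiguous gaps;
per-epoch means use half-open [start, end) windows and empty epochs are
filled by linear interpolation between neighbouring epoch means. Nights are
480–1176 epochs (4.0–9.8 h), 23 subjects by default; per-subject seeds are
spawned from the master seed, so cohorts are bit-reproducible. Missing
*stage* epochs, if present in real inputs, are filled by
previous-observation-carried-forward (stages are categorical). A stream
with more than 50 % of epochs missing rejects the night, mirroring the
usual night-exclusion rule.

What the simulator does **not** model: ultradian sleep-cycle architecture
(REM latency, cycle ordering), circadian heart-rate drift, movement
artifacts, or any dependence of device errors on anything but the true
stage. Passing tests on synthetic cohorts therefore demonstrate the
*mechanics* of the pipeline (no leakage, correct statistics, the cascade's
ability to exploit an informative signal), not field performance on real
tracker data.

`recovery_config()` is the preset for the recovery experiment: identical to
the defaults except the heart-rate means are widely separated
(52/62/74/88 bpm, SD 3), making the true stage recoverable from heart rate.
Under that regime the two-level model's held-out accuracy exceeds the
device pass-through's, averaged over 10 master seeds — the
parameter-recovery property in the acceptance suite (run at 6 subjects ×
150–250 epochs with singleton grids; the harness itself is
size-independent). With this strongly informative signal the one-level
XGBoost baselines also perform very well — the synthetic regime shows the
cascade *works*, not that it dominates all alternatives on real data, where
the published comparisons favour the cascade.

## Numerical and design choices

- Sex is coded 0 = male / 1 = female; the epoch index counts from sleep
  onset, not clock time.
- "Wake ratio" is the wake-epoch fraction of the night (distinct from WASO,
  which excludes wake before sleep onset).
- Kappa returns 1 when both sequences are constant and identical; MMCC
  returns 0 with a warning for single-class degenerate inputs.
- The stationary-distribution solver uses the left eigenvector of
  eigenvalue 1; the test oracle uses fixed-point iteration.
- Up sampling targets exact balance rather than approximate balance, for
  determinism and testability.
- Confusion matrices are column-normalized by ground-truth stage; absent
  truth stages yield NaN columns rather than a silent renormalization.
- All estimator seeds are reduced modulo 2³¹ before being handed to
  scikit-learn/XGBoost.

## Known limitations

- The harness is single-process; determinism is guaranteed only for
  single-process runs.
- The Anderson–Darling statistic on 4-valued ordinal data is heavily
  tie-corrected; its absolute scale is not comparable across cohort sizes.
- The MAB's field-relative normalization means it is only meaningful within
  one report's model set.
- No calibration of level-I probabilities; the 0.5 argmax threshold is
  fixed.
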
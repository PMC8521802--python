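# sleepcascade

Selective correction of consumer-wearable sleep staging.

Consumer activity trackers score sleep in 30-second epochs into four stages
— deep (1), light (2), REM (3) and wakefulness (4) — but their proprietary
staging is noticeably less accurate than a medical reference. This package
implements a two-level *selective correction* cascade for researchers who
work with such epoch-level tracker data: instead of re-scoring every epoch,
a **level-I binary classifier** f<sub>L1</sub> judges whether the device's
label for an epoch is a misclassification, and only flagged epochs are
handed to a **level-II four-class classifier** f<sub>L2</sub> that
re-labels them,

> y = f<sub>L2</sub>(f<sub>L1</sub>(**x**)),&nbsp;&nbsp; y ∈ {1, 2, 3, 4},

so epochs the device already got right are left untouched. Both levels
consume the same 21 features per epoch **x**: demographics (age, sex,
PSQI), the night's aggregated sleep metrics (TST, WASO, SE and the four
stage ratios), the epoch index, the device stage at offsets −3…+3, and
three heart-rate features (epoch mean and its two neighbouring first
differences). Level I can be gaussian naive Bayes, a random forest or a
linear-kernel SVM; level II is gradient-boosted trees (XGBoost), optionally
trained on a randomly up- or down-sampled copy of the training partition to
counter the dominance of light sleep. Resampling is applied to training
data only — never to an evaluation partition.

The package also ships:

- **`simkit`** — a synthetic cohort simulator (Markov-chain hypnograms with
  physiological stage proportions, a stage-conditional device-error
  process, noisy stage-dependent heart rate with missing samples), so every
  stage of the pipeline is testable without human data;
- **`prep`** — stream synchronization, vendor-vocabulary mapping (N3→1,
  N1/N2→2, R→3, W→4; deep/light/REM/wake→1–4), daily sleep metrics, the
  feature table and two-level label conversion;
- **`metrics`** — per-epoch accuracy, Cohen's Kappa, the multi-class
  Matthews correlation coefficient (MMCC), ground-truth-normalized
  confusion matrices, correcting power (CP) and over-correcting rate (OR),
  Bland–Altman bias with limits of agreement and trend test, the mean
  normalized absolute bias of stage durations
  MAB<sub>j</sub> = ¼ Σ<sub>i∈{W,L,D,R}</sub>
  (|e<sub>i,j</sub>| − min|e<sub>i</sub>|)/(max|e<sub>i</sub>| −
  min|e<sub>i</sub>|), Shannon diversity of stage labels and the k-sample
  Anderson–Darling dataset-shift statistic;
- **`harness`** — nested leave-one-subject-out cross-validation with inner
  10-fold grid search, evaluating up to thirteen models (the device
  pass-through, three one-level XGBoost baselines and nine two-level
  combinations) and assembling per-subject and aggregate reports.

## Worked example

`examples/03_agreement_metrics.py` fits a cascade (linear SVM detector +
up-sampled XGBoost re-classifier) on the first half of a simulated night
with a strongly stage-separated heart-rate signal and evaluates on the
second half:

```
device accuracy : 0.558
cascade accuracy: 0.731   kappa 0.593   MMCC 0.606
correcting power (device errors fixed)    : 0.392
over-correcting rate (correct epochs broken): 0.000
```

The device mislabels 44 % of epochs; the cascade corrects 39 % of those
errors while breaking none of the correct labels, lifting accuracy from
0.558 to 0.731. The other examples cover cohort simulation
(`01_simulate_cohort.py`), feature/label construction
(`02_features_and_labels.py`) and the full nested leave-one-subject-out
evaluation with MAB and imbalance/shift correlations (`04_nested_loso.py`).

A thin CLI mirrors the pipeline stages:

```bash
sleepcascade simulate  --subjects 23 --seed 1 --out cohort/
sleepcascade featurize --cohort cohort/ --out features.csv
sleepcascade loso      --cohort cohort/ --models all --seed 1 --out report/
sleepcascade summarize --report report/
```

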
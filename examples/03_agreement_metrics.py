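"""Epoch-wise and duration-wise agreement statistics on one subject.

Fits a two-level cascade (linear SVM detector + up-sampled XGBoost
re-classifier) on half a night and evaluates on the other half, then prints
the microscopic agreement statistics, comparing the corrected labels with
the raw device labels.
"""

import numpy as np

from sleepcascade import cascade, metrics, prep, simkit
from sleepcascade.cascade import REDUCED_GRIDS, ModelSpec
from sleepcascade.prep import StageSequence

record, _ = simkit.generate_subject(
    "S01", 900, simkit.recovery_config(), np.random.SeedSequence(3))
features = prep.build_features(record)
labels = prep.convert_labels(StageSequence(record.device),
                             StageSequence(record.reference))

half = record.n_epochs // 2
spec = ModelSpec(level1_algorithm="linear_svm", level2_resampling="up",
                 grids=REDUCED_GRIDS, seed=0)
model = cascade.fit_cascade(features.iloc[:half], labels.level1[:half],
                            labels.level2[:half], spec)
pred = cascade.predict_cascade(model, features.iloc[half:].reset_index(drop=True),
                               record.device[half:])

device, truth = record.device[half:], record.reference[half:]
rep = metrics.micro_report(device, pred.stages, truth)
print(f"device accuracy : {metrics.per_epoch_accuracy(device, truth):.3f}")
print(f"cascade accuracy: {rep.accuracy:.3f}   kappa {rep.kappa:.3f}   "
      f"MMCC {rep.mmcc:.3f}")
print(f"correcting power (device errors fixed)    : {rep.cp:.3f}")
print(f"over-correcting rate (correct epochs broken): {rep.or_rate:.3f}")
print("\nconfusion (% of each ground-truth stage):")
print(rep.confusion.round(1).to_string())
print("\nA useful cascade has high CP at low OR: it fixes many device "
      "errors\nwhile leaving correctly labeled epochs alone.")
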
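"""Simulate a synthetic cohort and inspect its statistical structure.

Builds a 5-subject cohort of 30-s-epoch sleep nights: a Markov-chain
hypnogram per subject, a device label stream corrupted by the configured
stage-conditional error matrix, and per-epoch mean heart rate. Prints the
pooled stage proportions (which should sit inside the physiological
intervals: light 40-60 %, REM 15-25 %, deep 15-20 %, wake 5-15 %) and the
empirical device-vs-truth agreement per stage.
"""

import numpy as np

from sleepcascade import simkit
from sleepcascade.prep import STAGE_NAMES, STAGES

cfg = simkit.SimulatorConfig(n_subjects=5, master_seed=42)
cohort = simkit.generate_cohort(cfg)

truth = np.concatenate([rec.reference for _, rec in cohort.subjects])
device = np.concatenate([rec.device for _, rec in cohort.subjects])

print(f"{len(cohort)} subjects, {len(truth)} pooled epochs")
print("\nstage      proportion   device agreement")
for code in STAGES:
    mask = truth == code
    print(f"{STAGE_NAMES[code]:<8}   {mask.mean():10.3f}   "
          f"{np.mean(device[mask] == code):16.3f}")
print("\nThe agreement column is the diagonal of the configured error "
      "matrix\n(e.g. light ~0.693): the device mislabels a third of light "
      "sleep and\nmost wakefulness, which is the error structure the "
      "cascade corrects.")
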
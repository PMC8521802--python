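import numpy as np
import pytest

from sleepcascade import prep, simkit
from sleepcascade.prep import AlignedRecord, Demographics, StageSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(n_epochs=200, seed=0, subject_id="S01",
                config: simkit.SimulatorConfig | None = None) -> AlignedRecord:
    cfg = config or simkit.SimulatorConfig(n_subjects=1,
                                           epochs_range=(n_epochs, n_epochs))
    record, _ = simkit.generate_subject(
        subject_id, n_epochs, cfg, np.random.SeedSequence(seed))
    return record


@pytest.fixture
def small_record():
    return make_record(n_epochs=120, seed=7)


@pytest.fixture
def tiny_cohort():
    cfg = simkit.SimulatorConfig(n_subjects=4, epochs_range=(80, 120),
                                 master_seed=11)
    return simkit.generate_cohort(cfg)


@pytest.fixture
def table2_sequences():
    """The six-epoch worked example of label conversion:
    device (4,4,2,2,3,3) vs reference (4,4,4,4,2,3)."""
    device = StageSequence(np.array([4, 4, 2, 2, 3, 3]))
    reference = StageSequence(np.array([4, 4, 4, 4, 2, 3]))
    return device, reference
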
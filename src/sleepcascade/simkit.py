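"""Synthetic cohort simulator.

Generates nights of sleep with the statistical structure the pipeline
assumes: a first-order Markov hypnogram whose stationary stage proportions
sit inside the physiological intervals (light 40-60 %, REM 15-25 %, deep
15-20 %, wake 5-15 %), a device-confusion corruption process that emulates a
consumer tracker's stage-conditional error structure, and noisy
stage-dependent heart rate with missing samples. Every quantity is
reproducible from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import prep
from .prep import (STAGE_DEEP, STAGE_LIGHT, STAGE_REM, STAGE_WAKE, STAGES,
                   AlignedRecord, Demographics, HeartRateSeries, StageSequence)

#: Physiological stage-proportion intervals for a normal night.
DEFAULT_TARGET_PROPORTIONS = {
    STAGE_LIGHT: (0.40, 0.60),
    STAGE_REM: (0.15, 0.25),
    STAGE_DEEP: (0.15, 0.20),
    STAGE_WAKE: (0.05, 0.15),
}

# Stationary distribution pinned at the (normalized) midpoints of the
# proportion intervals, indexed by stage code 1..4 (deep, light, REM, wake).
_MIDPOINTS = np.array([0.175, 0.50, 0.20, 0.10])
STATIONARY = _MIDPOINTS / _MIDPOINTS.sum()

#: Stage persistence of the default hypnogram chain: probability mass kept on
#: the current stage beyond the stationary mixture. 0.85 gives mean stage
#: bouts of a few minutes, the epoch-scale persistence real hypnograms show.
DEFAULT_PERSISTENCE = 0.85

#: Device error structure P(device = column | truth = row), stage order
#: deep, light, REM, wake. Cells follow a published consumer-tracker
#: confusion pattern (light-truth agreement 69.3 %, heavy wake->light and
#: deep<->light confusion); rows renormalized to sum to 1.
_FITBIT_CELLS = np.array([
    # device:  deep   light   rem    wake      truth:
    [0.609, 0.291, 0.029, 0.027],  # deep
    [0.216, 0.693, 0.059, 0.032],  # light
    [0.035, 0.317, 0.596, 0.053],  # REM
    [0.065, 0.503, 0.081, 0.350],  # wake
])
DEFAULT_ERROR_MATRIX = _FITBIT_CELLS / _FITBIT_CELLS.sum(axis=1, keepdims=True)


def _validate_rows(matrix: np.ndarray, name: str) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise ValueError(f"{name} must be 4x4, got {matrix.shape}")
    if (matrix < 0).any():
        raise ValueError(f"{name} has negative entries")
    sums = matrix.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError(f"{name} rows must sum to 1 within 1e-9, got {sums}")
    return matrix


@dataclass
class TransitionSpec:
    """First-order Markov chain over stage codes 1..4."""

    matrix: np.ndarray
    initial: np.ndarray

    def __post_init__(self):
        self.matrix = _validate_rows(self.matrix, "transition matrix")
        self.initial = np.asarray(self.initial, dtype=float)
        if self.initial.shape != (4,) or (self.initial < 0).any() \
                or abs(self.initial.sum() - 1) > 1e-9:
            raise ValueError("initial distribution must be a length-4 simplex vector")

    @classmethod
    def default(cls, persistence: float = DEFAULT_PERSISTENCE) -> "TransitionSpec":
        """Sticky chain T = p*I + (1-p) * 1 pi^T whose stationary
        distribution is exactly ``STATIONARY`` for any persistence p."""
        if not 0 <= persistence < 1:
            raise ValueError("persistence must be in [0, 1)")
        mat = (persistence * np.eye(4)
               + (1 - persistence) * np.tile(STATIONARY, (4, 1)))
        return cls(matrix=mat, initial=STATIONARY.copy())


@dataclass
class HeartRateSpec:
    """Per-stage mean bpm and gaussian noise SD for the per-second samples."""

    means: dict = field(default_factory=lambda: {
        STAGE_DEEP: 56.0, STAGE_LIGHT: 62.0, STAGE_REM: 68.0, STAGE_WAKE: 74.0})
    noise_sd: float = 4.0

    def __post_init__(self):
        if any(self.means.get(s, -1) <= 0 for s in STAGES):
            raise ValueError("heart-rate means must be positive for all 4 stages")
        if self.noise_sd < 0:
            raise ValueError("heart-rate noise SD must be non-negative")

    def mean_vector(self) -> np.ndarray:
        return np.array([self.means[s] for s in STAGES])


@dataclass
class DemographicsSpec:
    age_range: tuple = (20, 40)
    female_ratio: float = 0.5
    psqi_range: tuple = (1, 12)


@dataclass
class SimulatorConfig:
    n_subjects: int = 23
    epochs_range: tuple = (480, 1176)
    transition_spec: TransitionSpec = field(default_factory=TransitionSpec.default)
    target_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_TARGET_PROPORTIONS))
    error_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_ERROR_MATRIX.copy())
    hr_spec: HeartRateSpec = field(default_factory=HeartRateSpec)
    hr_missing_rate: float = 0.10
    demographics_spec: DemographicsSpec = field(default_factory=DemographicsSpec)
    master_seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.epochs_range
        if lo < 1 or hi < lo:
            raise ValueError("epochs_range must satisfy 1 <= min <= max")
        self.error_matrix = _validate_rows(self.error_matrix, "error matrix")
        if not 0 <= self.hr_missing_rate < 1:
            raise ValueError("hr_missing_rate must be in [0, 1)")


@dataclass
class Cohort:
    """A list of simulated subjects: (subject id, aligned record)."""

    subjects: list  # of (subject_id, AlignedRecord)
    config: SimulatorConfig | None = None

    def __post_init__(self):
        ids = [sid for sid, _ in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        if any(rec.n_epochs == 0 for _, rec in self.subjects):
            raise ValueError("every record must be non-empty")

    def __len__(self) -> int:
        return len(self.subjects)

    def subject_ids(self) -> list:
        return [sid for sid, _ in self.subjects]


def simulate_hypnogram(n_epochs: int, transition_spec: TransitionSpec,
                       seed) -> StageSequence:
    """Draw a night of stage codes from a first-order Markov chain."""
    if n_epochs < 0:
        raise ValueError("n_epochs must be non-negative")
    rng = np.random.default_rng(seed)
    if n_epochs == 0:
        return StageSequence(np.empty(0, dtype=int))
    cum = np.cumsum(transition_spec.matrix, axis=1)
    u = rng.random(n_epochs)
    stages = np.empty(n_epochs, dtype=int)
    state = int(np.searchsorted(np.cumsum(transition_spec.initial), u[0]))
    stages[0] = state + 1
    for t in range(1, n_epochs):
        state = int(np.searchsorted(cum[state], u[t]))
        stages[t] = state + 1
    return StageSequence(stages)


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector
    of eigenvalue 1, normalized to a probability vector)."""
    matrix = _validate_rows(matrix, "transition matrix")
    vals, vecs = np.linalg.eig(matrix.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = pi / pi.sum()
    return pi


def corrupt_stages(truth: StageSequence, error_matrix: np.ndarray,
                   seed) -> StageSequence:
    """Draw a device label for each epoch from the error matrix row of the
    true stage: output[n] ~ P(device | truth = truth[n])."""
    error_matrix = _validate_rows(error_matrix, "error matrix")
    if len(truth) == 0:
        return StageSequence(np.empty(0, dtype=int))
    rng = np.random.default_rng(seed)
    cum = np.cumsum(error_matrix, axis=1)
    u = rng.random(len(truth))
    rows = truth.stages - 1
    out = np.empty(len(truth), dtype=int)
    for s in range(4):
        mask = rows == s
        out[mask] = np.searchsorted(cum[s], u[mask]) + 1
    return StageSequence(out)


def simulate_heart_rate(truth: StageSequence, hr_spec: HeartRateSpec,
                        hr_missing_rate: float, seed,
                        n_gaps: int = 0, gap_seconds: int = 120) -> HeartRateSeries:
    """Per-second bpm over the hypnogram span.

    Each second's sample is the current stage's mean bpm plus gaussian noise.
    Missingness is i.i.d. sample dropout at ``hr_missing_rate``, optionally
    plus ``n_gaps`` contiguous gaps of ``gap_seconds`` (emulating the uneven
    sampling of tracker APIs).
    """
    if not 0 <= hr_missing_rate < 1:
        raise ValueError("hr_missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_sec = len(truth) * prep.EPOCH_SECONDS
    t = np.arange(n_sec, dtype=float)
    if n_sec == 0:
        return HeartRateSeries(t, t.copy())
    stage_per_sec = np.repeat(truth.stages, prep.EPOCH_SECONDS)
    bpm = hr_spec.mean_vector()[stage_per_sec - 1] \
        + rng.normal(0.0, hr_spec.noise_sd, n_sec)
    bpm = np.maximum(bpm, 1.0)  # bpm must stay positive
    if hr_missing_rate > 0:
        bpm[rng.random(n_sec) < hr_missing_rate] = np.nan
    for _ in range(n_gaps):
        start = rng.integers(0, max(n_sec - gap_seconds, 1))
        bpm[start:start + gap_seconds] = np.nan
    return HeartRateSeries(t, bpm)


def generate_subject(subject_id: str, n_epochs: int, config: SimulatorConfig,
                     seed_seq: np.random.SeedSequence):
    """One subject: truth hypnogram -> device corruption -> heart rate ->
    aligned record. Returns (record, truth sequence)."""
    s_hyp, s_err, s_hr, s_dem = seed_seq.spawn(4)
    truth = simulate_hypnogram(n_epochs, config.transition_spec, s_hyp)
    device = corrupt_stages(truth, config.error_matrix, s_err)
    hr = simulate_heart_rate(truth, config.hr_spec, config.hr_missing_rate, s_hr)
    rng = np.random.default_rng(s_dem)
    ds = config.demographics_spec
    demo = Demographics(
        age=int(rng.integers(ds.age_range[0], ds.age_range[1] + 1)),
        sex=int(rng.random() < ds.female_ratio),
        psqi=int(rng.integers(ds.psqi_range[0], ds.psqi_range[1] + 1)),
    )
    record = prep.align_and_interpolate(device, truth, hr, demographics=demo,
                                        subject_id=subject_id)
    return record, truth


def generate_cohort(config: SimulatorConfig) -> Cohort:
    """Simulate the full cohort; per-subject seeds are spawned
    deterministically from the master seed."""
    root = np.random.SeedSequence(config.master_seed)
    count_rng = np.random.default_rng(root.spawn(1)[0])
    subject_seqs = root.spawn(config.n_subjects)
    lo, hi = config.epochs_range
    subjects = []
    for i, seq in enumerate(subject_seqs):
        sid = f"S{i + 1:02d}"
        n_epochs = int(count_rng.integers(lo, hi + 1))
        record, _ = generate_subject(sid, n_epochs, config, seq)
        subjects.append((sid, record))
    return Cohort(subjects=subjects, config=config)


# ---------------------------------------------------------------------------
# presets and disk I/O

def recovery_config(master_seed: int = 0, n_subjects: int = 23,
                    epochs_range: tuple = (480, 1176)) -> SimulatorConfig:
    """Study conditions with a strongly stage-separated heart-rate signal.

    The wide spacing of the per-stage means (deep 52, light 62, REM 74,
    wake 88 bpm at SD 3) makes the true stage recoverable from heart rate,
    which is the regime in which selective correction can beat the device
    baseline; the device error structure is the default tracker confusion.
    """
    return SimulatorConfig(
        n_subjects=n_subjects,
        epochs_range=epochs_range,
        hr_spec=HeartRateSpec(
            means={STAGE_DEEP: 52.0, STAGE_LIGHT: 62.0,
                   STAGE_REM: 74.0, STAGE_WAKE: 88.0},
            noise_sd=3.0),
        master_seed=master_seed,
    )


def save_cohort(cohort: Cohort, out_dir) -> None:
    """Write one epochs CSV per subject plus a cohort manifest and, when a
    config is attached, a YAML snapshot of its scalar parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for sid, rec in cohort.subjects:
        rec.to_frame().to_csv(out / f"{sid}_epochs.csv", index=False)
        d = rec.demographics
        manifest.append({"subject_id": sid, "age": d.age, "sex": d.sex,
                         "psqi": d.psqi, "n_epochs": rec.n_epochs})
    pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False)
    if cohort.config is not None:
        cfg = cohort.config
        snapshot = {
            "n_subjects": cfg.n_subjects,
            "epochs_range": list(cfg.epochs_range),
            "hr_missing_rate": cfg.hr_missing_rate,
            "master_seed": cfg.master_seed,
            "transition_matrix": cfg.transition_spec.matrix.tolist(),
            "error_matrix": cfg.error_matrix.tolist(),
            "hr_means": {int(k): float(v) for k, v in cfg.hr_spec.means.items()},
            "hr_noise_sd": cfg.hr_spec.noise_sd,
        }
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(snapshot, fh)


def load_cohort(in_dir) -> Cohort:
    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.csv")
    subjects = []
    for row in manifest.itertuples():
        demo = Demographics(age=row.age, sex=int(row.sex), psqi=int(row.psqi))
        rec = prep.record_from_csv(src / f"{row.subject_id}_epochs.csv",
                                   demographics=demo, subject_id=row.subject_id)
        subjects.append((row.subject_id, rec))
    return Cohort(subjects=subjects)
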
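"""Preprocessing: stage-vocabulary mapping, stream alignment, daily sleep
metrics, the 21-column feature table and two-level label conversion.

Stage codes used throughout the package::

    1 = deep sleep (N3)
    2 = light sleep (N1 + N2)
    3 = REM sleep
    4 = wakefulness

Epochs are fixed 30-second scoring windows, indexed from 1 at sleep-record
start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGE_DEEP = 1
STAGE_LIGHT = 2
STAGE_REM = 3
STAGE_WAKE = 4
STAGES = (STAGE_DEEP, STAGE_LIGHT, STAGE_REM, STAGE_WAKE)
STAGE_NAMES = {STAGE_DEEP: "deep", STAGE_LIGHT: "light",
               STAGE_REM: "rem", STAGE_WAKE: "wake"}

EPOCH_SECONDS = 30

#: Fixed, documented column order of the feature table (M = 21).
FEATURE_COLUMNS = [
    # static (10): demographics + aggregated daily sleep metrics
    "age", "sex", "psqi",
    "tst_min", "waso_min", "se_percent",
    "wake_ratio", "light_ratio", "deep_ratio", "rem_ratio",
    # dynamic (11): epoch index, device-stage window n-3..n+3, heart rate
    "epoch_id",
    "stage_lag3", "stage_lag2", "stage_lag1", "stage_cur",
    "stage_lead1", "stage_lead2", "stage_lead3",
    "hr_mean", "hr_delta_prev", "hr_delta_next",
]

# vendor stage vocabularies -> codes
_DEVICE_VOCAB = {
    "deep sleep": STAGE_DEEP, "deep": STAGE_DEEP,
    "light sleep": STAGE_LIGHT, "light": STAGE_LIGHT,
    "rem sleep": STAGE_REM, "rem": STAGE_REM,
    "wakefulness": STAGE_WAKE, "wake": STAGE_WAKE, "awake": STAGE_WAKE,
}
_REFERENCE_VOCAB = {
    "n3": STAGE_DEEP, "stage n3": STAGE_DEEP,
    "n1": STAGE_LIGHT, "stage n1": STAGE_LIGHT,
    "n2": STAGE_LIGHT, "stage n2": STAGE_LIGHT,
    "r": STAGE_REM, "stage r": STAGE_REM,
    "w": STAGE_WAKE, "stage w": STAGE_WAKE,
}


class RecordRejected(Exception):
    """A record failed the >50 %-missing night-exclusion rule.

    ``stream`` names the offending data stream.
    """

    def __init__(self, stream: str, missing_fraction: float):
        self.stream = stream
        self.missing_fraction = missing_fraction
        super().__init__(
            f"stream {stream!r} has {missing_fraction:.0%} missing "
            "(rejection threshold is 50%)")


@dataclass
class StageSequence:
    """Per-subject vector of 30-s epoch stage codes, epochs numbered from 1."""

    stages: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        self.stages = np.asarray(self.stages, dtype=int)
        if self.stages.ndim != 1:
            raise ValueError("stages must be a 1-D vector")
        bad = ~np.isin(self.stages, STAGES)
        if bad.any():
            raise ValueError(
                f"stage codes must be in {{1,2,3,4}}; offending values "
                f"{np.unique(self.stages[bad])} at positions {np.where(bad)[0]}")

    @property
    def epoch_ids(self) -> np.ndarray:
        return np.arange(1, len(self.stages) + 1)

    def __len__(self) -> int:
        return len(self.stages)


@dataclass
class HeartRateSeries:
    """Per-second heart-rate samples; missing samples encoded as NaN bpm."""

    timestamps: np.ndarray  # seconds from record start
    bpm: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.bpm = np.asarray(self.bpm, dtype=float)
        if len(self.timestamps) != len(self.bpm):
            raise ValueError("timestamps and bpm must have equal length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        present = self.bpm[~np.isnan(self.bpm)]
        if (present <= 0).any():
            raise ValueError("bpm must be positive where present")


@dataclass
class Demographics:
    age: float
    sex: int  # 0 = male, 1 = female
    psqi: int

    def __post_init__(self):
        if self.sex not in (0, 1):
            raise ValueError("sex must be coded 0 (male) or 1 (female)")
        if not 0 <= self.psqi <= 21:
            raise ValueError("PSQI score must be in 0..21")


@dataclass
class AlignedRecord:
    """Synchronized per-epoch device stage, reference stage and mean heart
    rate, with subject demographics. No missing values after alignment."""

    subject_id: str
    device: np.ndarray
    reference: np.ndarray
    hr_mean: np.ndarray
    demographics: Demographics

    def __post_init__(self):
        self.device = np.asarray(self.device, dtype=int)
        self.reference = np.asarray(self.reference, dtype=int)
        self.hr_mean = np.asarray(self.hr_mean, dtype=float)
        n = len(self.device)
        if not (len(self.reference) == len(self.hr_mean) == n):
            raise ValueError("per-epoch vectors must have equal length")
        if np.isnan(self.hr_mean).any():
            raise ValueError("hr_mean must be gap-free after interpolation")

    @property
    def n_epochs(self) -> int:
        return len(self.device)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch_id": np.arange(1, self.n_epochs + 1),
            "fitbit_stage": self.device,
            "medical_stage": self.reference,
            "hr_mean_raw": self.hr_mean,
        })


@dataclass
class SleepMetrics:
    """Daily sleep metrics over one night (standard actigraphy definitions)."""

    tst_min: float
    waso_min: float
    se_percent: float
    wake_ratio: float
    light_ratio: float
    deep_ratio: float
    rem_ratio: float

    def __post_init__(self):
        total = (self.wake_ratio + self.light_ratio
                 + self.deep_ratio + self.rem_ratio)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stage ratios must sum to 1, got {total}")
        if not 0 <= self.se_percent <= 100:
            raise ValueError("sleep efficiency must be in [0, 100]")


@dataclass
class LabelSet:
    """Epoch-wise labels for the two classification levels.

    ``level1[n]`` is 1 iff the device stage disagrees with the reference at
    epoch n (misclassification indicator); ``level2`` is the reference stage.
    """

    level1: np.ndarray
    level2: np.ndarray


def map_stage_labels(raw_labels, source: str) -> StageSequence:
    """Map vendor stage strings to codes 1-4.

    ``source='device'`` accepts the consumer-tracker vocabulary (deep/light/
    REM sleep, wakefulness); ``source='reference'`` accepts AASM stage names
    (N1, N2 -> light, N3 -> deep, R, W).
    """
    if source == "device":
        vocab = _DEVICE_VOCAB
    elif source == "reference":
        vocab = _REFERENCE_VOCAB
    else:
        raise ValueError(f"source must be 'device' or 'reference', got {source!r}")
    codes = []
    for pos, token in enumerate(raw_labels):
        key = str(token).strip().lower()
        if key not in vocab:
            raise ValueError(
                f"unknown {source} stage token {token!r} at position {pos}")
        codes.append(vocab[key])
    return StageSequence(np.array(codes, dtype=int))


def segment_count(duration_s: float) -> int:
    """Number of whole 30-s epochs in a sleep record of the given duration."""
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    return int(duration_s // EPOCH_SECONDS)


def epoch_hr_means(hr: HeartRateSeries, n_epochs: int) -> np.ndarray:
    """Mean bpm per epoch; epochs with no usable sample are NaN.

    A sample with timestamp t belongs to epoch ``t // 30 + 1`` (half-open
    [start, end) windows, so no sample is counted twice).
    """
    means = np.full(n_epochs, np.nan)
    ok = ~np.isnan(hr.bpm)
    idx = (hr.timestamps[ok] // EPOCH_SECONDS).astype(int)
    in_range = (idx >= 0) & (idx < n_epochs)
    idx, vals = idx[in_range], hr.bpm[ok][in_range]
    if len(idx):
        sums = np.bincount(idx, weights=vals, minlength=n_epochs)
        counts = np.bincount(idx, minlength=n_epochs)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means


def align_and_interpolate(device: StageSequence, reference: StageSequence,
                          hr: HeartRateSeries,
                          demographics: Demographics | None = None,
                          subject_id: str = "",
                          max_missing: float = 0.5) -> AlignedRecord:
    """Synchronize device/reference/heart-rate streams into one record.

    Epochs are restricted to the overlap of the two stage streams (both are
    assumed to start at the same sleep onset). Per-epoch heart rate is the
    mean of in-epoch samples; epochs without samples are filled by linear
    interpolation between neighbouring epoch means (edge epochs take the
    nearest available mean). A stream with more than ``max_missing`` of its
    epochs missing triggers :class:`RecordRejected`, mirroring the night
    exclusion rule.
    """
    n = min(len(device), len(reference))
    if n == 0:
        raise ValueError("stage streams have no overlapping epochs")
    means = epoch_hr_means(hr, n)
    missing = np.isnan(means)
    frac = missing.mean()
    if frac > max_missing:
        raise RecordRejected("heart_rate", frac)
    if missing.all():
        raise RecordRejected("heart_rate", 1.0)
    if missing.any():
        filled = (pd.Series(means)
                  .interpolate(method="linear", limit_direction="both")
                  .to_numpy())
    else:
        filled = means
    if demographics is None:
        demographics = Demographics(age=30, sex=0, psqi=5)
    return AlignedRecord(subject_id=subject_id,
                         device=device.stages[:n],
                         reference=reference.stages[:n],
                         hr_mean=filled,
                         demographics=demographics)


def fill_missing_stages(stages: np.ndarray) -> np.ndarray:
    """Previous-observation-carried-forward fill for missing stage epochs
    (encoded as 0 or NaN); stages are categorical so linear interpolation is
    undefined. Leading gaps take the first observed stage."""
    s = pd.Series(np.asarray(stages, dtype=float))
    s = s.replace(0, np.nan).ffill().bfill()
    if s.isna().any():
        raise ValueError("stage stream is entirely missing")
    return s.to_numpy().astype(int)


def compute_daily_metrics(stages: StageSequence) -> SleepMetrics:
    """Daily sleep metrics from a hypnogram.

    TST = 0.5 min x count(stage != wake); WASO = 0.5 min x count(wake epochs
    after the first non-wake epoch); SE = TST / time in bed x 100; each stage
    ratio = stage count / total epochs.
    """
    s = stages.stages
    n = len(s)
    if n == 0:
        raise ValueError("cannot compute sleep metrics of an empty night")
    sleep = s != STAGE_WAKE
    tst = 0.5 * sleep.sum()
    onset = np.argmax(sleep) if sleep.any() else None
    waso = 0.5 * (s[onset:] == STAGE_WAKE).sum() if onset is not None else 0.0
    return SleepMetrics(
        tst_min=float(tst),
        waso_min=float(waso),
        se_percent=float(tst / (0.5 * n) * 100),
        wake_ratio=float((s == STAGE_WAKE).mean()),
        light_ratio=float((s == STAGE_LIGHT).mean()),
        deep_ratio=float((s == STAGE_DEEP).mean()),
        rem_ratio=float((s == STAGE_REM).mean()),
    )


def _padded_shift(x: np.ndarray, offset: int) -> np.ndarray:
    # replication padding at sequence boundaries
    idx = np.clip(np.arange(len(x)) + offset, 0, len(x) - 1)
    return x[idx]


def build_features(record: AlignedRecord,
                   metrics: SleepMetrics | None = None) -> pd.DataFrame:
    """Build the N x 21 feature table for one subject-night.

    Ten static columns (age, sex, PSQI and the seven daily sleep metrics) are
    constant within the night; eleven dynamic columns carry the epoch index,
    the device stage at offsets -3..+3 (replication-padded at the record
    boundaries), the epoch mean heart rate and its first differences against
    the preceding and succeeding epochs.
    """
    n = record.n_epochs
    if n < 1:
        raise ValueError("record must contain at least one epoch")
    if metrics is None:
        # daily metrics are device-derived features: they must be available
        # at prediction time, when no reference labels exist
        metrics = compute_daily_metrics(StageSequence(record.device))
    d = record.demographics
    hr = record.hr_mean
    cols = {
        "age": np.full(n, float(d.age)),
        "sex": np.full(n, float(d.sex)),
        "psqi": np.full(n, float(d.psqi)),
        "tst_min": np.full(n, metrics.tst_min),
        "waso_min": np.full(n, metrics.waso_min),
        "se_percent": np.full(n, metrics.se_percent),
        "wake_ratio": np.full(n, metrics.wake_ratio),
        "light_ratio": np.full(n, metrics.light_ratio),
        "deep_ratio": np.full(n, metrics.deep_ratio),
        "rem_ratio": np.full(n, metrics.rem_ratio),
        "epoch_id": np.arange(1, n + 1, dtype=float),
        "hr_mean": hr,
        "hr_delta_prev": hr - _padded_shift(hr, -1),
        "hr_delta_next": _padded_shift(hr, +1) - hr,
    }
    for off in range(-3, 4):
        name = ("stage_cur" if off == 0
                else f"stage_lag{-off}" if off < 0 else f"stage_lead{off}")
        cols[name] = _padded_shift(record.device, off).astype(float)
    table = pd.DataFrame(cols)[FEATURE_COLUMNS]
    assert table.shape[1] == 21
    return table


def convert_labels(device: StageSequence, reference: StageSequence) -> LabelSet:
    """Epoch-wise label conversion for the two classification levels.

    Level I: 0 where the device agrees with the reference (correct
    classification), 1 otherwise. Level II: the reference stage itself.
    """
    if len(device) != len(reference):
        raise ValueError("device and reference sequences differ in length")
    return LabelSet(level1=(device.stages != reference.stages).astype(int),
                    level2=reference.stages.copy())


def record_to_csv(record: AlignedRecord, path) -> None:
    record.to_frame().to_csv(path, index=False)


def record_from_csv(path, demographics: Demographics,
                    subject_id: str = "") -> AlignedRecord:
    df = pd.read_csv(path)
    return AlignedRecord(subject_id=subject_id,
                         device=df["fitbit_stage"].to_numpy(),
                         reference=df["medical_stage"].to_numpy(),
                         hr_mean=df["hr_mean_raw"].to_numpy(),
                         demographics=demographics)
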
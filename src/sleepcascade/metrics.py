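"""Evaluation statistics for epoch-wise sleep staging.

Microscopic measures compare predicted and reference stages epoch by epoch:
overall per-epoch accuracy, Cohen's Kappa, the multi-class Matthews
correlation coefficient (MMCC), a ground-truth-normalized confusion matrix,
and the two cascade-specific measures — correcting power (CP, the fraction
of device-mislabeled epochs the model fixes) and over-correcting rate (OR,
the fraction of device-correct epochs the model breaks).

Macroscopic measures compare total stage durations per night: Bland–Altman
bias and limits of agreement with a trend test, and the mean normalized
absolute bias (MAB) which min–max-normalizes each model's absolute stage
bias against the field of models and averages over the four stages.

Dataset characterization: Shannon diversity of a test set's stage labels
(class imbalance) and the k-sample Anderson–Darling statistic between
training and test stage distributions (dataset shift).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import matthews_corrcoef

from .prep import STAGES, STAGE_NAMES, StageSequence

STAGE_ORDER = ("wake", "light", "deep", "rem")  # reporting order W, L, D, R


def _as_array(x) -> np.ndarray:
    if isinstance(x, StageSequence):
        return x.stages
    return np.asarray(x)


def _paired(pred, truth):
    p, t = _as_array(pred), _as_array(truth)
    if len(p) != len(t):
        raise ValueError(f"length mismatch: {len(p)} vs {len(t)}")
    if len(p) == 0:
        raise ValueError("empty input")
    return p, t


@dataclass
class MicroReport:
    accuracy: float
    kappa: float
    mmcc: float
    confusion: pd.DataFrame
    cp: float
    or_rate: float


@dataclass
class BAResult:
    """Bland–Altman agreement between a model and the ground truth.

    Differences are truth - model, so a positive bias means the model
    underestimates. LOA = bias +/- 1.96 SD of the differences.
    """

    bias: float
    loa_lower: float
    loa_upper: float
    t_stat: float
    t_pvalue: float
    trend_slope: float
    trend_pvalue: float


@dataclass
class ShiftStats:
    sdi: float
    ad: float


def per_epoch_accuracy(pred, truth) -> float:
    """Fraction of epochs whose predicted stage equals the reference stage."""
    p, t = _paired(pred, truth)
    return float(np.mean(p == t))


def cohens_kappa(pred, truth) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e), with expected
    agreement p_e from the product of marginals. When both raters are
    constant and identical (p_e = p_o = 1) agreement is perfect: returns 1."""
    p, t = _paired(pred, truth)
    classes = np.union1d(p, t)
    n = len(p)
    p_o = np.mean(p == t)
    p_e = sum((p == c).mean() * (t == c).mean() for c in classes)
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return float((p_o - p_e) / (1 - p_e))


def mmcc(pred, truth) -> float:
    """Multi-class Matthews correlation coefficient (the R_K statistic of
    the full contingency table): 1 = perfect classification, -1 = perfect
    misclassification, 0 = random guess. Degenerate single-class inputs are
    defined as 0."""
    p, t = _paired(pred, truth)
    if len(np.union1d(p, t)) < 2:
        warnings.warn("single class in both inputs; MMCC defined as 0")
        return 0.0
    return float(matthews_corrcoef(t, p))


def confusion_matrix(pred, truth) -> pd.DataFrame:
    """4x4 percent table with columns = ground-truth stages and rows =
    predicted stages; each column of an observed truth stage sums to 100.
    Columns of truth stages absent from the input are NaN."""
    p, t = _paired(pred, truth)
    counts = np.zeros((4, 4))
    for r in STAGES:
        for c in STAGES:
            counts[r - 1, c - 1] = np.sum((p == r) & (t == c))
    col_tot = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(col_tot > 0, counts / col_tot * 100, np.nan)
    names = [STAGE_NAMES[s] for s in STAGES]
    return pd.DataFrame(pct, index=names, columns=names)


def correcting_power(device, pred, truth) -> float:
    """Among epochs the device mislabels, the fraction the model corrects.
    NaN (with a warning) when the device made no errors."""
    d, t = _paired(device, truth)
    p, _ = _paired(pred, truth)
    wrong = d != t
    if not wrong.any():
        warnings.warn("device made no errors; correcting power undefined")
        return float("nan")
    return float(np.mean(p[wrong] == t[wrong]))


def over_correcting_rate(device, pred, truth) -> float:
    """Among epochs the device labels correctly, the fraction the model
    breaks. NaN (with a warning) when the device got nothing right."""
    d, t = _paired(device, truth)
    p, _ = _paired(pred, truth)
    right = d == t
    if not right.any():
        warnings.warn("device has no correct epochs; over-correcting rate undefined")
        return float("nan")
    return float(np.mean(p[right] != t[right]))


def micro_report(device, pred, truth) -> MicroReport:
    return MicroReport(
        accuracy=per_epoch_accuracy(pred, truth),
        kappa=cohens_kappa(pred, truth),
        mmcc=mmcc(pred, truth),
        confusion=confusion_matrix(pred, truth),
        cp=correcting_power(device, pred, truth),
        or_rate=over_correcting_rate(device, pred, truth),
    )


def delta_improvement(m_proposal: float, m_fitbit: float) -> float:
    """Signed percent change of a model's metric against the device
    baseline: (M_proposal - M_fitbit) / M_fitbit x 100. A negative value is
    a reduction of that magnitude."""
    if m_fitbit == 0:
        raise ValueError("baseline metric is zero; percent change undefined")
    return float((m_proposal - m_fitbit) / m_fitbit * 100.0)


def stage_durations(stages) -> dict:
    """Minutes spent in each stage: 0.5 min per 30-s epoch. Keys are the
    stage names wake/light/deep/rem; an empty night gives all zeros."""
    s = _as_array(stages)
    return {STAGE_NAMES[code]: float(0.5 * np.sum(s == code)) for code in STAGES}


def bland_altman(model_values, true_values) -> BAResult:
    """Bland–Altman comparison of per-subject minutes (n >= 3 pairs).

    Computes the mean difference (truth - model), the 1.96-SD limits of
    agreement, a two-tailed one-sample t-test of the bias against 0, and a
    least-squares trend of the differences on the pair means."""
    m = np.asarray(model_values, dtype=float)
    t = np.asarray(true_values, dtype=float)
    if len(m) != len(t):
        raise ValueError("paired vectors differ in length")
    if len(m) < 3:
        raise ValueError("Bland–Altman needs at least 3 pairs")
    diff = t - m
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    tt = stats.ttest_1samp(diff, 0.0)
    means = (t + m) / 2.0
    if np.ptp(means) == 0:
        slope, slope_p = 0.0, float("nan")
    else:
        fit = stats.linregress(means, diff)
        slope, slope_p = float(fit.slope), float(fit.pvalue)
    return BAResult(bias=bias,
                    loa_lower=bias - 1.96 * sd,
                    loa_upper=bias + 1.96 * sd,
                    t_stat=float(tt.statistic), t_pvalue=float(tt.pvalue),
                    trend_slope=slope, trend_pvalue=slope_p)


def make_bias_table(biases: dict) -> pd.DataFrame:
    """Assemble the signed per-stage bias table e_ij.

    ``biases`` maps model id -> {stage name -> signed bias in minutes} over
    the four stages W, L, D, R; returns a DataFrame with stages as rows and
    models as columns."""
    table = pd.DataFrame(biases)
    missing = set(STAGE_ORDER) - set(table.index)
    if missing:
        raise ValueError(f"bias table missing stages {sorted(missing)}")
    return table.loc[list(STAGE_ORDER)]


def mab(bias_table: pd.DataFrame, model_id) -> float:
    """Mean normalized absolute bias of one model against the field.

    For each stage i, the model's |e_ij| is min–max-normalized across all
    models ((|e_ij| - min_j|e_ij|) / (max_j - min_j)); the MAB is the mean of
    the four stage terms. A stage where all models tie (max = min)
    contributes 0."""
    if model_id not in bias_table.columns:
        raise ValueError(f"model {model_id!r} not in bias table")
    if bias_table.shape[1] < 2:
        raise ValueError("MAB needs at least 2 models for normalization")
    abs_e = bias_table.abs()
    lo, hi = abs_e.min(axis=1), abs_e.max(axis=1)
    span = hi - lo
    terms = np.where(span > 0, (abs_e[model_id] - lo) / span.replace(0, np.nan), 0.0)
    return float(np.mean(terms))


def shannon_diversity(labels) -> float:
    """Shannon diversity H = -sum p_i ln p_i of the stage label proportions;
    lower means a more imbalanced night. Ranges over [0, ln 4]."""
    s = _as_array(labels)
    if len(s) == 0:
        raise ValueError("empty label vector")
    _, counts = np.unique(s, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def ad_shift(train_labels, test_labels) -> float:
    """Two-sample Anderson–Darling statistic (Scholz–Stephens k-sample form,
    midrank tie correction) between training-set and test-set stage codes
    treated as an ordinal variable. Higher = larger distribution shift."""
    a, b = _as_array(train_labels), _as_array(test_labels)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty label vector")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # p-value capping outside its table
        res = stats.anderson_ksamp([a.astype(float), b.astype(float)],
                                   midrank=True)
    return float(res.statistic)


def plot_bland_altman(model_values, true_values, ax=None, title=None):
    """Render a Bland–Altman plot: differences (truth - model) against pair
    means, with the bias line, the two limits of agreement and the fitted
    trend. Requires matplotlib (the optional ``plot`` extra)."""
    import matplotlib.pyplot as plt

    res = bland_altman(model_values, true_values)
    m = np.asarray(model_values, float)
    t = np.asarray(true_values, float)
    means, diffs = (t + m) / 2.0, t - m
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(means, diffs, s=18, alpha=0.8)
    ax.axhline(res.bias, color="k", label=f"bias {res.bias:.1f}")
    for loa in (res.loa_lower, res.loa_upper):
        ax.axhline(loa, color="k", linestyle="--")
    if np.ptp(means) > 0:
        xs = np.linspace(means.min(), means.max(), 20)
        intercept = diffs.mean() - res.trend_slope * means.mean()
        ax.plot(xs, intercept + res.trend_slope * xs, color="C1",
                label=f"trend p={res.trend_pvalue:.2g}")
    ax.set_xlabel("mean of methods (min)")
    ax.set_ylabel("truth - model (min)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    return ax


def correlate_performance(metric_by_subject, stat_by_subject) -> tuple:
    """Pearson correlation (r, two-tailed p) between a per-subject
    performance metric and a per-subject dataset statistic."""
    x = np.asarray(metric_by_subject, dtype=float)
    y = np.asarray(stat_by_subject, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors differ in length")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors; r undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
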
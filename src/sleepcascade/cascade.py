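"""Two-level selective-correction cascade.

A level-I binary classifier decides, epoch by epoch, whether the device's
stage label is a misclassification (1) or correct (0). Epochs flagged as
misclassified are handed to a level-II four-class classifier that re-labels
them; unflagged epochs keep the device label untouched. Both levels consume
the same 21-column feature table.

Level-I algorithms: gaussian naive Bayes, random forest, linear-kernel SVM
(features z-scored with training statistics inside the SVM pipeline only).
Level II is gradient-boosted trees (XGBoost), optionally trained on a
randomly up- or down-sampled copy of the training partition — resampling is
applied to training data only, never to evaluation partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

from .prep import FEATURE_COLUMNS, STAGES, StageSequence

LEVEL1_ALGORITHMS = ("naive_bayes", "random_forest", "linear_svm")
RESAMPLING_STRATEGIES = ("none", "up", "down")

#: Default hyperparameter grids for the inner grid search.
DEFAULT_GRIDS = {
    "naive_bayes": {"var_smoothing": [1e-9, 1e-6]},
    "random_forest": {"n_estimators": [100, 500],
                      "max_features": ["sqrt", 0.333]},
    "linear_svm": {"C": [0.01, 0.1, 1.0, 10.0]},
    "xgboost": {"max_depth": [3, 6, 9],
                "learning_rate": [0.05, 0.1, 0.3],
                "n_estimators": [50, 100, 200]},
}

#: Singleton grids for quick, deterministic runs (no tuning).
REDUCED_GRIDS = {
    "naive_bayes": {"var_smoothing": [1e-9]},
    "random_forest": {"n_estimators": [100], "max_features": ["sqrt"]},
    "linear_svm": {"C": [1.0]},
    "xgboost": {"max_depth": [3], "learning_rate": [0.1], "n_estimators": [100]},
}


@dataclass
class ModelSpec:
    """Configuration of one two-level model (or one-level baseline)."""

    level1_algorithm: str = "linear_svm"
    level2_algorithm: str = "xgboost"
    level1_resampling: str = "none"   # exposed but off by default
    level2_resampling: str = "none"
    grids: dict = field(default_factory=lambda: {k: dict(v) for k, v in
                                                 DEFAULT_GRIDS.items()})
    inner_cv_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.level1_algorithm not in LEVEL1_ALGORITHMS:
            raise ValueError(f"unknown level-I algorithm {self.level1_algorithm!r}")
        if self.level2_algorithm != "xgboost":
            raise ValueError("level-II algorithm must be 'xgboost'")
        for r in (self.level1_resampling, self.level2_resampling):
            if r not in RESAMPLING_STRATEGIES:
                raise ValueError(f"resampling must be one of "
                                 f"{RESAMPLING_STRATEGIES}, got {r!r}")


def default_params(algorithm: str, grids: dict | None = None) -> dict:
    """First point of the (given or default) grid, in grid order."""
    grid = (grids or DEFAULT_GRIDS)[algorithm]
    return {k: v[0] for k, v in grid.items()}


def resample_training_set(features: pd.DataFrame, labels, strategy: str,
                          seed) -> tuple:
    """Random up/down resampling to exact class balance.

    ``down`` subsamples every class without replacement to the minimum class
    count; ``up`` resamples every class with replacement to the maximum
    class count (classes already at the maximum are kept as-is); ``none`` is
    the identity. Rows are always exact copies of original rows — no
    synthetic interpolation.
    """
    if strategy not in RESAMPLING_STRATEGIES:
        raise ValueError(f"unknown resampling strategy {strategy!r}")
    y = np.asarray(labels)
    if len(features) != len(y):
        raise ValueError("features and labels differ in length")
    if len(y) == 0:
        raise ValueError("cannot resample an empty training set")
    if strategy == "none":
        return features, y
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.min() if strategy == "down" else counts.max()
    keep = []
    for c, cnt in zip(classes, counts):
        idx = np.flatnonzero(y == c)
        if cnt == target:
            keep.append(idx)
        elif strategy == "down":
            keep.append(rng.choice(idx, size=target, replace=False))
        else:
            keep.append(rng.choice(idx, size=target, replace=True))
    sel = np.concatenate(keep)
    return features.iloc[sel].reset_index(drop=True), y[sel]


def build_level1_estimator(algorithm: str, params: dict, seed):
    """Instantiate an unfitted level-I estimator for the given grid point."""
    if algorithm == "naive_bayes":
        return GaussianNB(**params)
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=_to_int_seed(seed),
                                      n_jobs=1, **params)
    if algorithm == "linear_svm":
        # the SVM is the only learner that gets feature normalization
        return Pipeline([
            ("scale", StandardScaler()),
            ("svm", LinearSVC(random_state=_to_int_seed(seed), dual="auto",
                              max_iter=20000, **params)),
        ])
    raise ValueError(f"unknown level-I algorithm {algorithm!r}")


def build_level2_estimator(params: dict, seed):
    """Unfitted four-class XGBoost classifier (labels encoded 0..3)."""
    return XGBClassifier(random_state=_to_int_seed(seed), n_jobs=1,
                         verbosity=0, **params)


def _to_int_seed(seed) -> int:
    if seed is None:
        return 0
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0] % (2**31))
    return int(seed) % (2**31)


def _check_features(features: pd.DataFrame):
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    return features[FEATURE_COLUMNS]


def fit_level1(features: pd.DataFrame, level1_labels, spec: ModelSpec,
               params: dict | None = None):
    """Fit the misclassification detector on (optionally resampled)
    training data at a fixed grid point (hyperparameter selection lives in
    the evaluation harness)."""
    X = _check_features(features)
    y = np.asarray(level1_labels)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("level-I labels must be in {0, 1}")
    if len(np.unique(y)) < 2:
        raise ValueError("level-I training labels contain a single class")
    if params is None:
        params = default_params(spec.level1_algorithm, spec.grids)
    X, y = resample_training_set(X, y, spec.level1_resampling, spec.seed)
    est = build_level1_estimator(spec.level1_algorithm, params, spec.seed)
    est.fit(X.to_numpy(), y)
    return est


def fit_level2(features: pd.DataFrame, level2_labels, spec: ModelSpec,
               params: dict | None = None):
    """Fit the four-stage re-classifier; resampling (per spec) applies to
    this training partition only."""
    X = _check_features(features)
    y = np.asarray(level2_labels)
    if not set(np.unique(y)) <= set(STAGES):
        raise ValueError("level-II labels must be stage codes 1..4")
    if params is None:
        params = default_params("xgboost", spec.grids)
    X, y = resample_training_set(X, y, spec.level2_resampling, spec.seed)
    est = build_level2_estimator(params, spec.seed)
    est.fit(X.to_numpy(), y - 1)
    return est


def fit_onelevel_baseline(features: pd.DataFrame, level2_labels,
                          resampling: str, spec: ModelSpec,
                          params: dict | None = None):
    """One-level baseline: re-classify every epoch with four-class XGBoost
    (the training task is identical to level II's)."""
    one = ModelSpec(level1_algorithm=spec.level1_algorithm,
                    level2_resampling=resampling, grids=spec.grids,
                    inner_cv_folds=spec.inner_cv_folds, seed=spec.seed)
    return fit_level2(features, level2_labels, one, params=params)


@dataclass
class CascadeModel:
    """A fitted two-level model: detector + re-classifier + provenance."""

    level1: object
    level2: object
    spec: ModelSpec
    chosen_params: dict = field(default_factory=dict)

    def predict_level1(self, features: pd.DataFrame) -> np.ndarray:
        X = _check_features(features).to_numpy()
        return np.asarray(self.level1.predict(X)).astype(int)

    def predict_level2(self, features: pd.DataFrame) -> np.ndarray:
        X = _check_features(features).to_numpy()
        return np.asarray(self.level2.predict(X)).astype(int) + 1


def fit_cascade(features: pd.DataFrame, level1_labels, level2_labels,
                spec: ModelSpec, level1_params: dict | None = None,
                level2_params: dict | None = None) -> CascadeModel:
    l1 = fit_level1(features, level1_labels, spec, params=level1_params)
    l2 = fit_level2(features, level2_labels, spec, params=level2_params)
    return CascadeModel(level1=l1, level2=l2, spec=spec,
                        chosen_params={"level1": level1_params or
                                       default_params(spec.level1_algorithm, spec.grids),
                                       "level2": level2_params or
                                       default_params("xgboost", spec.grids)})


def predict_cascade(model: CascadeModel, features: pd.DataFrame,
                    device_stages) -> StageSequence:
    """Selective correction: keep the device label where level I predicts 0,
    substitute the level-II prediction where it predicts 1."""
    device = device_stages.stages if isinstance(device_stages, StageSequence) \
        else np.asarray(device_stages, dtype=int)
    if len(features) != len(device):
        raise ValueError("feature rows and device stages differ in length")
    flags = model.predict_level1(features)
    out = device.copy()
    if flags.any():
        relabeled = model.predict_level2(features.loc[flags.astype(bool)])
        out[flags.astype(bool)] = relabeled
    return StageSequence(out)
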
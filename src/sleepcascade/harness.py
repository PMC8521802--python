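"""Nested leave-one-subject-out cross-validation.

Each outer iteration holds one subject's whole night out as the test set and
merges the remaining subjects into the training set; hyperparameters are
tuned on the training set alone by grid search with stratified 10-fold inner
CV, with resampling applied inside each inner training fold only. The fitted
models are then evaluated on the untouched held-out subject. Thirteen models
are available: the device pass-through baseline, three one-level four-class
re-classifiers (XGB, XGBd, XGBu) and nine two-level selective-correction
combinations ({NB, RF, SVM} at level I x {none, down, up} resampling at
level II).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from . import cascade, metrics, prep
from .cascade import ModelSpec, CascadeModel
from .prep import StageSequence
from .simkit import Cohort

log = logging.getLogger(__name__)

_L1_SHORT = {"naive_bayes": "NB", "random_forest": "RF", "linear_svm": "SVM"}
_RESAMP_SUFFIX = {"none": "", "down": "d", "up": "u"}

#: name -> descriptor: ("fitbit",) | ("onelevel", resamp) |
#: ("twolevel", level1_algorithm, level2_resampling)
MODEL_CATALOG = {"Fitbit": ("fitbit",)}
for _r, _suf in _RESAMP_SUFFIX.items():
    MODEL_CATALOG[f"XGB{_suf}"] = ("onelevel", _r)
for _alg, _short in _L1_SHORT.items():
    for _r, _suf in _RESAMP_SUFFIX.items():
        MODEL_CATALOG[f"{_short}+XGB{_suf}"] = ("twolevel", _alg, _r)

ALL_MODELS = list(MODEL_CATALOG)


@dataclass
class CVSplit:
    index: int
    test_subject: str
    train_subjects: list


def make_loso_splits(cohort: Cohort) -> list:
    """One split per subject, deterministic ordering by subject id."""
    ids = sorted(cohort.subject_ids())
    if len(ids) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [CVSplit(index=i, test_subject=sid,
                    train_subjects=[s for s in ids if s != sid])
            for i, sid in enumerate(ids)]


def _grid_points(grid: dict) -> list:
    keys = list(grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


def grid_search_inner(train_features: pd.DataFrame, train_labels,
                      spec: ModelSpec, level: str = "level1") -> dict:
    """Choose a hyperparameter point by stratified inner-CV grid search.

    Scoring is overall accuracy at level I and Cohen's Kappa at level II;
    ties break to the earlier point in grid order. Resampling, when
    configured, is applied to each inner training fold only — validation
    folds are never resampled. A singleton grid is returned directly.
    """
    algorithm = spec.level1_algorithm if level == "level1" else "xgboost"
    resampling = (spec.level1_resampling if level == "level1"
                  else spec.level2_resampling)
    grid = spec.grids[algorithm]
    points = _grid_points(grid)
    if not points:
        raise ValueError("empty hyperparameter grid")
    if len(points) == 1:
        return points[0]

    X = train_features[prep.FEATURE_COLUMNS].to_numpy()
    y = np.asarray(train_labels)
    Xdf = train_features[prep.FEATURE_COLUMNS].reset_index(drop=True)
    min_count = np.bincount(np.unique(y, return_inverse=True)[1]).min()
    n_folds = max(2, min(spec.inner_cv_folds, int(min_count)))
    seed = cascade._to_int_seed(spec.seed)
    if min_count >= 2:
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)

    best_point, best_score = None, -np.inf
    for pt in points:
        fold_scores = []
        for tr_idx, va_idx in cv.split(X, y):
            X_tr, y_tr = cascade.resample_training_set(
                Xdf.iloc[tr_idx], y[tr_idx], resampling, seed)
            if level == "level1":
                est = cascade.build_level1_estimator(algorithm, pt, seed)
                est.fit(X_tr.to_numpy(), y_tr)
                pred = est.predict(X[va_idx])
                fold_scores.append(np.mean(pred == y[va_idx]))
            else:
                est = cascade.build_level2_estimator(pt, seed)
                est.fit(X_tr.to_numpy(), y_tr - 1)
                pred = est.predict(X[va_idx]) + 1
                fold_scores.append(metrics.cohens_kappa(pred, y[va_idx]))
        score = float(np.mean(fold_scores))
        if score > best_score:  # strict: first-in-grid wins ties
            best_point, best_score = pt, score
    return best_point


@dataclass
class CVReport:
    """Per-subject and aggregate results of one nested LOSO run."""

    per_subject: pd.DataFrame   # subject, model, accuracy, kappa, mmcc, cp, or_rate
    shift: pd.DataFrame         # subject, sdi, ad
    durations: pd.DataFrame     # subject, model (incl. 'Reference'), wake..rem min
    chosen_params: dict = field(default_factory=dict)
    n_subjects_requested: int = 0

    @property
    def models(self) -> list:
        return [m for m in self.per_subject["model"].unique()]

    @property
    def n_outer_iterations(self) -> int:
        return self.per_subject["subject"].nunique()

    def aggregate(self) -> pd.DataFrame:
        """Mean +/- SD of each microscopic metric across subjects."""
        g = self.per_subject.groupby("model", sort=False)
        out = {}
        for m in ("accuracy", "kappa", "mmcc", "cp", "or_rate"):
            out[f"{m}_mean"] = g[m].mean()
            out[f"{m}_sd"] = g[m].std(ddof=1)
        return pd.DataFrame(out)

    def bias_table(self) -> pd.DataFrame:
        """Signed per-stage duration bias e_ij (minutes, truth - model),
        averaged across subjects; rows W, L, D, R, columns models."""
        ref = (self.durations[self.durations["model"] == "Reference"]
               .set_index("subject"))
        biases = {}
        for model in self.models:
            dm = (self.durations[self.durations["model"] == model]
                  .set_index("subject"))
            biases[model] = {
                stage: float((ref[stage] - dm[stage]).mean())
                for stage in metrics.STAGE_ORDER}
        return metrics.make_bias_table(biases)

    def bland_altman_results(self) -> dict:
        """(model, stage) -> BAResult over per-subject stage durations."""
        ref = (self.durations[self.durations["model"] == "Reference"]
               .set_index("subject"))
        out = {}
        for model in self.models:
            dm = (self.durations[self.durations["model"] == model]
                  .set_index("subject")).loc[ref.index]
            for stage in metrics.STAGE_ORDER:
                out[(model, stage)] = metrics.bland_altman(
                    dm[stage].to_numpy(), ref[stage].to_numpy())
        return out

    def mab_per_model(self) -> pd.Series:
        table = self.bias_table()
        return pd.Series({m: metrics.mab(table, m) for m in table.columns},
                         name="mab")

    def correlations(self) -> pd.DataFrame:
        """Pearson r (and p) of each metric against test-set Shannon
        diversity and training/test Anderson–Darling shift, per model."""
        merged = self.per_subject.merge(self.shift, on="subject")
        rows = []
        for model in self.models:
            sub = merged[merged["model"] == model]
            for metric_name in ("accuracy", "kappa", "mmcc", "cp", "or_rate"):
                for stat_name in ("sdi", "ad"):
                    vals = sub[[metric_name, stat_name]].dropna()
                    try:
                        r, p = metrics.correlate_performance(
                            vals[metric_name], vals[stat_name])
                    except ValueError:
                        r, p = np.nan, np.nan
                    rows.append({"model": model, "metric": metric_name,
                                 "statistic": stat_name, "r": r, "p": p})
        return pd.DataFrame(rows)


def _prepare_subject(record):
    feats = prep.build_features(record)
    labels = prep.convert_labels(StageSequence(record.device),
                                 StageSequence(record.reference))
    return feats, labels.level1, labels.level2, record.device, record.reference


def run_nested_loso(cohort: Cohort, model_names=None, master_seed: int = 0,
                    grids: dict | None = None,
                    inner_cv_folds: int = 10) -> CVReport:
    """Run the full nested LOSO evaluation for the requested models.

    Within each outer split, level-I fits are shared across models with the
    same level-I algorithm, and the four-class XGBoost fits are shared
    between a one-level baseline and the level-II re-classifiers with the
    same resampling strategy (their training task is identical).
    Subjects whose preprocessing fails are skipped with a logged warning.
    """
    if model_names is None:
        model_names = ALL_MODELS
    unknown = [m for m in model_names if m not in MODEL_CATALOG]
    if unknown:
        raise ValueError(f"unknown models {unknown}; choose from {ALL_MODELS}")
    grids = grids or cascade.DEFAULT_GRIDS

    prepared, skipped = {}, []
    for sid, record in cohort.subjects:
        try:
            prepared[sid] = _prepare_subject(record)
        except (ValueError, prep.RecordRejected) as exc:
            log.warning("subject %s skipped: %s", sid, exc)
            skipped.append(sid)
    kept = Cohort(subjects=[(sid, rec) for sid, rec in cohort.subjects
                            if sid in prepared])
    splits = make_loso_splits(kept)
    split_seeds = np.random.SeedSequence(master_seed).spawn(len(splits))

    rows, dur_rows, shift_rows, chosen = [], [], [], {}
    for split, seq in zip(splits, split_seeds):
        feats_tr = pd.concat([prepared[s][0] for s in split.train_subjects],
                             ignore_index=True)
        y1_tr = np.concatenate([prepared[s][1] for s in split.train_subjects])
        y2_tr = np.concatenate([prepared[s][2] for s in split.train_subjects])
        feats_te, _, _, device_te, truth_te = prepared[split.test_subject]

        child = {name: s for name, s in
                 zip(("l1", "l2"), seq.spawn(2))}
        l1_fits, l2_fits = {}, {}

        def level1_fit(alg):
            if alg not in l1_fits:
                spec = ModelSpec(level1_algorithm=alg, grids=grids,
                                 inner_cv_folds=inner_cv_folds,
                                 seed=child["l1"])
                pt = grid_search_inner(feats_tr, y1_tr, spec, level="level1")
                est = cascade.fit_level1(feats_tr, y1_tr, spec, params=pt)
                chosen[(split.test_subject, "level1", alg)] = pt
                l1_fits[alg] = est
            return l1_fits[alg]

        def level2_fit(resamp):
            if resamp not in l2_fits:
                spec = ModelSpec(level2_resampling=resamp, grids=grids,
                                 inner_cv_folds=inner_cv_folds,
                                 seed=child["l2"])
                pt = grid_search_inner(feats_tr, y2_tr, spec, level="level2")
                est = cascade.fit_level2(feats_tr, y2_tr, spec, params=pt)
                chosen[(split.test_subject, "level2", resamp)] = pt
                l2_fits[resamp] = est
            return l2_fits[resamp]

        for name in model_names:
            desc = MODEL_CATALOG[name]
            if desc[0] == "fitbit":
                pred = device_te.copy()
            elif desc[0] == "onelevel":
                est = level2_fit(desc[1])
                pred = est.predict(feats_te[prep.FEATURE_COLUMNS].to_numpy()) + 1
            else:
                _, alg, resamp = desc
                model = CascadeModel(level1=level1_fit(alg),
                                     level2=level2_fit(resamp),
                                     spec=ModelSpec(level1_algorithm=alg,
                                                    level2_resampling=resamp,
                                                    grids=grids))
                pred = cascade.predict_cascade(model, feats_te,
                                               device_te).stages
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # degenerate CP/OR -> NaN
                rep = metrics.micro_report(device_te, pred, truth_te)
            rows.append({"subject": split.test_subject, "model": name,
                         "accuracy": rep.accuracy, "kappa": rep.kappa,
                         "mmcc": rep.mmcc, "cp": rep.cp,
                         "or_rate": rep.or_rate})
            dur_rows.append({"subject": split.test_subject, "model": name,
                             **metrics.stage_durations(pred)})
        dur_rows.append({"subject": split.test_subject, "model": "Reference",
                         **metrics.stage_durations(truth_te)})
        shift_rows.append({"subject": split.test_subject,
                           "sdi": metrics.shannon_diversity(truth_te),
                           "ad": metrics.ad_shift(y2_tr, truth_te)})
        log.info("outer iteration %d/%d (test subject %s) done",
                 split.index + 1, len(splits), split.test_subject)

    return CVReport(per_subject=pd.DataFrame(rows),
                    shift=pd.DataFrame(shift_rows),
                    durations=pd.DataFrame(dur_rows),
                    chosen_params=chosen,
                    n_subjects_requested=len(cohort))


def summarize(report: CVReport, baseline: str = "Fitbit") -> pd.DataFrame:
    """Per-model mean +/- SD of accuracy/Kappa/MMCC, paired two-tailed
    t-tests against the device baseline across subjects, and percent-change
    columns of each mean against the baseline's."""
    if report.per_subject.empty:
        raise ValueError("empty report")
    wide = {m: report.per_subject.pivot(index="subject", columns="model",
                                        values=m)
            for m in ("accuracy", "kappa", "mmcc")}
    have_baseline = baseline in wide["accuracy"].columns
    rows = []
    for model in report.models:
        row = {"model": model}
        for m in ("accuracy", "kappa", "mmcc"):
            col = wide[m][model]
            row[f"{m}_mean"] = col.mean()
            row[f"{m}_sd"] = col.std(ddof=1)
            if have_baseline:
                base = wide[m][baseline]
                if model == baseline:
                    row[f"{m}_t"], row[f"{m}_p"] = 0.0, 1.0
                    row[f"{m}_delta_pct"] = 0.0
                else:
                    t = stats.ttest_rel(col, base)
                    row[f"{m}_t"], row[f"{m}_p"] = float(t.statistic), float(t.pvalue)
                    row[f"{m}_delta_pct"] = metrics.delta_improvement(
                        col.mean(), base.mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
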
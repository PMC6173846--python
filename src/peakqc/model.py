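"""Train, tune, select and apply the peak-quality classifier.

The classification unit is one endogenous/standard transition pair,
described by its 52 QC features; the binary outcome is the analyst
vocabulary 'ok' / 'flag', with **flag as the positive class** everywhere
(sensitivity is the rate at which genuinely poor peaks are caught).

Training follows the conventional supervised-QC recipe: hold out a
stratified validation fraction (default 20%), impute missing features by
training-set medians, mean-center and scale by the standard deviation, tune
each algorithm's hyper-parameters by tenfold cross-validation repeated 3
times, select the grid point with the best chosen metric (accuracy or ROC
AUC), and refit on the full training subset. Five algorithm families are
supported: regularized logistic regression, a regularized random forest,
K-nearest neighbours, and SVMs with linear and polynomial kernels.

The "regularized" random forest is a plain random forest wrapped in an
importance-floor feature-selection pass: features whose impurity importance
falls below a floor (a fraction of the largest importance) are dropped and
the forest refit on the survivors, trading a little variance for a simpler,
less overfit model.

Cross-validation folds are stratified by class and, by default, grouped by
run: all pairs of one run land in the same fold, because pairs within a run
share chromatography and are not independent.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import (GridSearchCV, StratifiedGroupKFold,
                                     StratifiedKFold, train_test_split)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import (CountExceedsRuns, PeakQCError, SchemaMismatch,
                     SingleClass)
from .features import KEY_COLUMNS, feature_names

ALGORITHMS = ("logistic_regularized", "random_forest_regularized", "knn",
              "svm_linear", "svm_polynomial")

#: fixed preference order used to break metric ties deterministically
TIE_BREAK_ORDER = ("random_forest_regularized", "knn", "svm_polynomial",
                   "svm_linear", "logistic_regularized")

DEFAULT_THRESHOLD = 0.5
POSITIVE = "flag"


class RegularizedRandomForest(ClassifierMixin, BaseEstimator):
    """Random forest with an importance-penalized feature-selection pass.

    A first forest is fit on all features; features with impurity
    importance below ``importance_floor`` times the largest importance are
    dropped and a second forest is refit on the survivors. Predictions come
    from the second forest.
    """

    def __init__(self, n_estimators=100, max_features="sqrt",
                 importance_floor=0.01, random_state=None):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.importance_floor = importance_floor
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        rf = RandomForestClassifier(n_estimators=self.n_estimators,
                                    max_features=self.max_features,
                                    random_state=self.random_state)
        rf.fit(X, y)
        imp = rf.feature_importances_
        floor = self.importance_floor * (imp.max() if imp.max() > 0 else 1.0)
        support = imp >= floor
        if not support.any():
            support = np.ones_like(support, dtype=bool)
        self.support_ = support
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators, max_features=self.max_features,
            random_state=self.random_state)
        self.forest_.fit(X[:, support], y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(np.asarray(X)[:, self.support_])

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X)[:, self.support_])


def _algorithm(name: str, seed: int) -> tuple[BaseEstimator, dict]:
    """Estimator + documented hyper-parameter grid for one family."""
    if name == "logistic_regularized":
        return (LogisticRegression(max_iter=5000, random_state=seed),
                {"clf__C": [0.01, 0.1, 1.0, 10.0]})
    if name == "random_forest_regularized":
        return (RegularizedRandomForest(n_estimators=100, random_state=seed),
                {"clf__importance_floor": [0.01, 0.05],
                 "clf__max_features": ["sqrt", 0.3]})
    if name == "knn":
        return (KNeighborsClassifier(),
                {"clf__n_neighbors": [3, 5, 7, 11, 15]})
    if name == "svm_linear":
        return (SVC(kernel="linear", probability=True, random_state=seed),
                {"clf__C": [0.1, 1.0, 10.0]})
    if name == "svm_polynomial":
        return (SVC(kernel="poly", probability=True, random_state=seed),
                {"clf__C": [0.1, 1.0, 10.0], "clf__degree": [2, 3]})
    raise PeakQCError(f"unknown algorithm {name!r}; choose from {ALGORITHMS}")


@dataclass
class QCModel:
    """A fitted peak-quality classifier plus everything needed to apply it.

    Preprocessing (median imputation, centering/scaling) lives inside the
    pipeline and was fit on training data only. ``threshold`` is the flag
    class-probability cutoff (flag iff p >= threshold), default 0.5.
    """

    algorithm: str
    metric: str
    pipeline: Pipeline
    features: list
    dropped_features: list
    best_params: dict
    cv_summary: pd.DataFrame
    seed: int
    threshold: float = DEFAULT_THRESHOLD
    grouped_cv: bool = True

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise PeakQCError("threshold must lie in (0, 1)")

    @property
    def model_id(self) -> str:
        return f"{self.algorithm}-seed{self.seed}"

    @property
    def cv_score(self) -> float:
        """Mean cross-validated score of the selected hyper-parameters."""
        return float(self.cv_summary["score"].mean())

    def flag_probability(self, rows: pd.DataFrame) -> np.ndarray:
        X = _feature_matrix(rows, self.features)
        proba = self.pipeline.predict_proba(X)
        flag_col = list(self.pipeline.classes_).index(POSITIVE)
        return proba[:, flag_col]


@dataclass
class EvaluationReport:
    """Validation metrics with flag as the positive class."""

    algorithm: str
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    confusion: dict            # tp, fp, tn, fn
    probabilities: np.ndarray
    cv_score: float = math.nan

    @property
    def n(self) -> int:
        return sum(self.confusion.values())


def _feature_matrix(rows: pd.DataFrame, features: Sequence[str]) -> pd.DataFrame:
    missing = [f for f in features if f not in rows.columns]
    if missing:
        raise SchemaMismatch(f"rows lack trained features: {missing}")
    return rows[list(features)]


def _require_both_classes(y: pd.Series) -> None:
    if y.nunique() < 2:
        raise SingleClass(f"need both ok and flag rows, got only {set(y)}")


def split_train_validation(rows: pd.DataFrame, fraction: float = 0.2,
                           seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/validation split on the Status column.

    ``fraction`` is the validation share (default 20%). A fraction of 0
    returns an empty validation frame with a warning.
    """
    if len(rows) < 10:
        raise PeakQCError("need >= 10 annotated rows to split")
    _require_both_classes(rows["Status"])
    if fraction == 0:
        warnings.warn("validation fraction 0: no held-out data")
        return rows.reset_index(drop=True), rows.iloc[0:0].copy()
    tr, va = train_test_split(rows, test_size=fraction, random_state=seed,
                              stratify=rows["Status"])
    return tr.reset_index(drop=True), va.reset_index(drop=True)


def _cv_splits(y: np.ndarray, groups: Optional[np.ndarray], n_splits: int,
               n_repeats: int, seed: int) -> list:
    """Stratified (optionally run-grouped) k-fold splits, repeated."""
    splits = []
    class_min = int(pd.Series(y).value_counts().min())
    for rep in range(n_repeats):
        if groups is not None:
            k = min(n_splits, len(np.unique(groups)))
            if k < 2:
                groups = None  # single run: fall back to ungrouped folds
        if groups is None:
            k = min(n_splits, class_min)
        k = max(k, 2)
        if groups is not None:
            cv = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                      random_state=seed + rep)
            splits.extend(cv.split(np.zeros(len(y)), y, groups))
        else:
            cv = StratifiedKFold(n_splits=k, shuffle=True,
                                 random_state=seed + rep)
            splits.extend(cv.split(np.zeros(len(y)), y))
    return splits


def train(rows: pd.DataFrame, algorithm: str = "random_forest_regularized",
          metric: str = "accuracy", seed: int = 0, grouped_cv: bool = True,
          n_splits: int = 10, n_repeats: int = 3,
          threshold: float = DEFAULT_THRESHOLD) -> QCModel:
    """Tune and fit one classifier family on annotated feature rows.

    Rows need the 52 feature columns plus Status; FileName (run id) enables
    run-grouped folds. Features with zero variance or no observed value in
    the training rows are dropped (and recorded on the model). Given one
    seed the chosen hyper-parameters and fitted model are reproducible.
    """
    if metric not in ("accuracy", "roc_auc"):
        raise PeakQCError("metric must be 'accuracy' or 'roc_auc'")
    y = rows["Status"].astype(str)
    _require_both_classes(y)
    if len(rows) < 30:
        warnings.warn(f"training on only {len(rows)} rows; >= 30 recommended")

    feats = [f for f in feature_names() if f in rows.columns]
    if not feats:
        raise SchemaMismatch("rows contain no registry feature columns")
    X_all = rows[feats]
    dropped = [f for f in feats
               if X_all[f].notna().sum() == 0 or X_all[f].std(skipna=True) == 0
               or np.isnan(X_all[f].std(skipna=True))]
    for f in dropped:
        warnings.warn(f"dropping degenerate feature {f!r}")
    feats = [f for f in feats if f not in dropped]
    X = rows[feats]

    groups = rows["FileName"].to_numpy() if (grouped_cv and "FileName" in rows) else None
    splits = _cv_splits(y.to_numpy(), groups, n_splits, n_repeats, seed)

    est, grid = _algorithm(algorithm, seed)
    pipe = Pipeline([("impute", SimpleImputer(strategy="median")),
                     ("scale", StandardScaler()),
                     ("clf", est)])
    scoring = metric if metric == "accuracy" else "roc_auc"
    search = GridSearchCV(pipe, grid, scoring=scoring, cv=splits, refit=True)
    search.fit(X, y)

    res = search.cv_results_
    best = search.best_index_
    per_fold = [res[f"split{i}_test_score"][best] for i in range(len(splits))]
    cv_summary = pd.DataFrame({"fold": np.arange(len(splits)), "score": per_fold})
    return QCModel(algorithm=algorithm, metric=metric,
                   pipeline=search.best_estimator_, features=feats,
                   dropped_features=dropped, best_params=search.best_params_,
                   cv_summary=cv_summary, seed=seed, threshold=threshold,
                   grouped_cv=groups is not None)


def predict(model: QCModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Score feature rows: flag probability and thresholded status.

    A pair is flagged iff its flag class probability is >= the model
    threshold (probability exactly at the threshold flags).
    """
    p = model.flag_probability(rows)
    out = rows[[c for c in KEY_COLUMNS if c in rows.columns]].copy()
    out["flag_probability"] = p
    out["status"] = np.where(p >= model.threshold, "flag", "ok")
    out["model_id"] = model.model_id
    return out


def evaluate(model: QCModel, rows: pd.DataFrame) -> EvaluationReport:
    """Confusion-matrix metrics of the model on annotated rows."""
    _require_both_classes(rows["Status"])
    p = model.flag_probability(rows)
    pred = p >= model.threshold
    truth = (rows["Status"].astype(str) == POSITIVE).to_numpy()
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    fn = int(np.sum(~pred & truth))
    auc = float(roc_auc_score(truth, p))
    return EvaluationReport(
        algorithm=model.algorithm,
        accuracy=(tp + tn) / len(rows),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        auc=auc, confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        probabilities=p, cv_score=model.cv_score)


def compare_models(train_rows: pd.DataFrame, validation_rows: pd.DataFrame,
                   algorithms: Sequence[str] = ALGORITHMS,
                   metric: str = "accuracy", seed: int = 0,
                   grouped_cv: bool = True,
                   threshold: float = DEFAULT_THRESHOLD
                   ) -> tuple[list[EvaluationReport], QCModel]:
    """Train every requested family on identical folds, rank by the
    cross-validated metric and return all validation reports plus the
    winning model. Ties break by the documented preference order."""
    models: dict[str, QCModel] = {}
    reports: list[EvaluationReport] = []
    for algo in algorithms:
        m = train(train_rows, algorithm=algo, metric=metric, seed=seed,
                  grouped_cv=grouped_cv, threshold=threshold)
        models[algo] = m
        reports.append(evaluate(m, validation_rows))
    order = {a: i for i, a in enumerate(TIE_BREAK_ORDER)}
    ranked = sorted(reports,
                    key=lambda r: (-models[r.algorithm].cv_score,
                                   order.get(r.algorithm, len(order))))
    return ranked, models[ranked[0].algorithm]


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    table: pd.DataFrame  # cutoff, sensitivity, specificity


def roc_analysis(model: QCModel, rows: pd.DataFrame) -> RocResult:
    """ROC over all distinct probability cutoffs, AUC by the trapezoid
    rule, and a per-cutoff sensitivity/specificity table for threshold
    selection."""
    _require_both_classes(rows["Status"])
    p = model.flag_probability(rows)
    truth = (rows["Status"].astype(str) == POSITIVE).to_numpy().astype(int)
    fpr, tpr, thr = roc_curve(truth, p)
    auc = float(np.trapezoid(tpr, fpr))
    table = pd.DataFrame({"cutoff": thr, "sensitivity": tpr,
                          "specificity": 1.0 - fpr})
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, table=table)


def learning_curve(rows: pd.DataFrame, run_counts: Sequence[int],
                   repeats: int = 5, seed: int = 0,
                   algorithm: str = "random_forest_regularized",
                   metric: str = "accuracy") -> pd.DataFrame:
    """Model performance versus number of annotated runs.

    For each requested count, samples that many runs without replacement
    ``repeats`` times, trains on the sampled runs and evaluates accuracy on
    the held-out runs (on the training runs themselves when none are held
    out). Returns per-count mean and a normal-approximation 95% resampling
    CI (NaN when repeats == 1).
    """
    runs = sorted(rows["FileName"].unique())
    if len(runs) < 2:
        raise PeakQCError("learning curve needs >= 2 runs")
    rng = np.random.default_rng(seed)
    records = []
    for count in run_counts:
        if count > len(runs):
            raise CountExceedsRuns(f"{count} > {len(runs)} available runs")
        scores = []
        for rep in range(repeats):
            chosen = list(rng.choice(runs, size=count, replace=False))
            tr = rows[rows["FileName"].isin(chosen)]
            held = rows[~rows["FileName"].isin(chosen)]
            if tr["Status"].nunique() < 2:
                continue  # degenerate resample: skip, do not fabricate
            m = train(tr, algorithm=algorithm, metric=metric,
                      seed=seed + rep, n_repeats=1)
            target = held if len(held) and held["Status"].nunique() == 2 else tr
            scores.append(evaluate(m, target).accuracy)
        mean = float(np.mean(scores)) if scores else math.nan
        if len(scores) > 1:
            half = 1.96 * float(np.std(scores, ddof=1)) / math.sqrt(len(scores))
        else:
            half = math.nan
        records.append({"n_runs": count, "n_pairs_mean":
                        float(len(rows) / len(runs) * count),
                        "score_mean": mean, "ci_low": mean - half,
                        "ci_high": mean + half, "n_resamples": len(scores)})
    return pd.DataFrame(records)


def feature_importance(model: QCModel, rows: pd.DataFrame, seed: int = 0,
                       n_repeats: int = 5) -> pd.DataFrame:
    """Permutation importance of each retained feature, normalized so the
    top feature scores 100. Algorithm-agnostic: works for every family."""
    X = _feature_matrix(rows, model.features)
    y = rows["Status"].astype(str)
    r = permutation_importance(model.pipeline, X, y, n_repeats=n_repeats,
                               random_state=seed, scoring="accuracy")
    imp = np.maximum(r.importances_mean, 0.0)
    top = imp.max()
    scaled = imp / top * 100.0 if top > 0 else imp
    return (pd.DataFrame({"feature": model.features, "importance": scaled})
            .sort_values("importance", ascending=False, kind="mergesort")
            .reset_index(drop=True))


def marginal_cases(predictions: pd.DataFrame,
                   band: tuple[float, float] = (0.35, 0.65)) -> pd.DataFrame:
    """Predictions whose flag probability lies inside the gray-zone band,
    sorted by ascending distance from 0.5 (most ambiguous first)."""
    lo, hi = band
    sel = predictions[(predictions["flag_probability"] >= lo)
                      & (predictions["flag_probability"] <= hi)].copy()
    sel["distance_from_half"] = (sel["flag_probability"] - 0.5).abs()
    return (sel.sort_values("distance_from_half", kind="mergesort")
            .reset_index(drop=True))


# --- model archive ---------------------------------------------------------

def save_model(model: QCModel, dirpath) -> Path:
    """Persist a model archive: fitted pipeline + JSON metadata."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.pipeline, d / "pipeline.joblib")
    meta = {"format_version": 1, "algorithm": model.algorithm,
            "metric": model.metric, "threshold": model.threshold,
            "seed": model.seed, "grouped_cv": model.grouped_cv,
            "features": model.features,
            "dropped_features": model.dropped_features,
            "best_params": {k: v for k, v in model.best_params.items()},
            "cv_scores": model.cv_summary["score"].tolist()}
    (d / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return d


def load_model(dirpath) -> QCModel:
    d = Path(dirpath)
    meta = json.loads((d / "model.json").read_text())
    pipeline = joblib.load(d / "pipeline.joblib")
    cv = pd.DataFrame({"fold": np.arange(len(meta["cv_scores"])),
                       "score": meta["cv_scores"]})
    return QCModel(algorithm=meta["algorithm"], metric=meta["metric"],
                   pipeline=pipeline, features=meta["features"],
                   dropped_features=meta["dropped_features"],
                   best_params=meta["best_params"], cv_summary=cv,
                   seed=meta["seed"], threshold=meta["threshold"],
                   grouped_cv=meta["grouped_cv"])
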
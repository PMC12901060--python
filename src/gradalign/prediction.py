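"""Nested cross-validated prediction with CV-consistent confound removal.

Protocol: 10 times repeated 5-fold outer CV; within every outer training
partition an inner 5-fold grid search selects the hyperparameters; a
confound-removal model (per-feature linear regression on the confounds) and
a feature standardizer are fit on the outer training rows only and applied
to both partitions.  Regression reports the out-of-sample coefficient of
determination R^2; classification reports accuracy and ROC AUC.

The learners themselves are scikit-learn's (ridge regression/classifier,
linear and RBF SVMs, random forests); this module's contract is the nested
protocol, the leakage control, the hyperparameter grids, and the scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import Ridge, RidgeClassifier
from sklearn.metrics import accuracy_score, r2_score, roc_auc_score
from sklearn.model_selection import (GridSearchCV, KFold, RepeatedKFold,
                                     RepeatedStratifiedKFold)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FeatureTable",
    "CVConfig",
    "PredictionResult",
    "ConfoundRegressor",
    "fit_confound_remover",
    "apply_confound_remover",
    "nested_cv_regression",
    "binarize_by_median",
    "nested_cv_classification",
    "score_derivative",
]

CLASSIFIER_NAMES = ("ridge", "linear-svm", "rbf-svm", "random-forest")


@dataclass
class FeatureTable:
    """Aligned feature/target/confound arrays for one prediction task."""

    features: np.ndarray
    target: np.ndarray
    confounds: Optional[np.ndarray] = None
    subject_ids: Optional[Sequence[str]] = None
    confound_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, float)
        self.target = np.asarray(self.target, float).ravel()
        n = self.features.shape[0]
        if self.target.size != n:
            raise ValueError("target length does not match feature rows")
        if self.confounds is not None:
            self.confounds = np.atleast_2d(np.asarray(self.confounds, float))
            if self.confounds.shape[0] != n:
                self.confounds = self.confounds.T
            if self.confounds.shape[0] != n:
                raise ValueError("confound rows do not match feature rows")
        for arr, name in ((self.features, "features"), (self.target, "target")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contain non-finite values")


@dataclass
class CVConfig:
    """Nested cross-validation protocol and hyperparameter grids."""

    outer_folds: int = 5
    outer_repeats: int = 10
    inner_folds: int = 5
    ridge_alpha_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.001, 10000, 50))
    svm_c_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-4, 1e4, 10))
    rbf_gamma_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-9, 1e4, 10))
    rf_max_depth_grid: tuple = (5, 10, 20, None)
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        for grid in (self.ridge_alpha_grid, self.svm_c_grid, self.rbf_gamma_grid):
            if len(grid) == 0 or np.any(np.asarray(grid, float) <= 0):
                raise ValueError("hyperparameter grids must be non-empty, positive")


@dataclass
class PredictionResult:
    """Per-fold scores plus the Fig-style summary (mean across all folds;
    sd of the per-repeat means)."""

    scores: pd.DataFrame  # columns: repeat, fold, score [, auc]
    mean_score: float
    sd_score: float
    scenario: str
    model: str
    n_align: Optional[int] = None
    mean_auc: Optional[float] = None
    sd_auc: Optional[float] = None


class ConfoundRegressor(BaseEstimator, TransformerMixin):
    """Per-feature linear confound removal (intercept + linear terms).

    ``fit`` learns, for every feature column, an ordinary least-squares
    model on the confounds; ``transform`` subtracts the model prediction.
    Training residuals are exactly orthogonal to every confound column.
    """

    def fit(self, X, y=None, confounds=None) -> "ConfoundRegressor":
        X = np.asarray(X, float)
        c = self._as_matrix(confounds, X.shape[0])
        # identically-zero confounds carry no information: intercept-only
        self.active_ = (np.any(c != 0, axis=0) if c.size
                        else np.zeros(c.shape[1], bool))
        design = self._design(c)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("rank-deficient confound design matrix")
        self.coef_, *_ = np.linalg.lstsq(design, X, rcond=None)
        self.n_confounds_ = design.shape[1] - 1
        return self

    def transform(self, X, confounds=None) -> np.ndarray:
        X = np.asarray(X, float)
        c = self._as_matrix(confounds, X.shape[0])
        if c.shape[1] != self.active_.size:
            raise ValueError("confound count differs from fit time")
        return X - self._design(c) @ self.coef_

    def _design(self, c: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones(c.shape[0]), c[:, self.active_]])

    @staticmethod
    def _as_matrix(confounds, n_rows: int) -> np.ndarray:
        if confounds is None:
            return np.zeros((n_rows, 0))
        c = np.atleast_2d(np.asarray(confounds, float))
        if c.shape[0] != n_rows:
            c = c.T
        if c.shape[0] != n_rows:
            raise ValueError("confound rows do not match feature rows")
        return c


def fit_confound_remover(train_features, train_confounds) -> ConfoundRegressor:
    train_features = np.asarray(train_features, float)
    if train_confounds is not None:
        q = np.atleast_2d(np.asarray(train_confounds, float))
        q_cols = q.shape[1] if q.shape[0] == train_features.shape[0] else q.shape[0]
    else:
        q_cols = 0
    if train_features.shape[0] < q_cols + 2:
        raise ValueError("need at least q + 2 training rows for confound removal")
    return ConfoundRegressor().fit(train_features, confounds=train_confounds)


def apply_confound_remover(remover: ConfoundRegressor, features, confounds):
    return remover.transform(features, confounds=confounds)


def _select_confounds(table: FeatureTable, scenario) -> Optional[np.ndarray]:
    """Resolve a scenario (None/"none", column indices, or column names) to a
    confound sub-matrix; None means no removal."""
    if scenario is None or scenario == "none" or scenario == ():
        return None
    if table.confounds is None:
        raise ValueError("scenario requests confound removal but the table "
                         "has no confounds")
    if isinstance(scenario, str):
        scenario = [scenario]
    cols = []
    for s in scenario:
        if isinstance(s, str):
            if table.confound_names is None:
                raise ValueError("confound names not set on the table")
            cols.append(list(table.confound_names).index(s))
        else:
            cols.append(int(s))
    return table.confounds[:, cols]


def _base_pipeline(estimator, standardize: bool) -> Pipeline:
    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("model", estimator))
    return Pipeline(steps)


def _scenario_label(scenario) -> str:
    if scenario is None or scenario == "none" or scenario == ():
        return "none"
    if isinstance(scenario, str):
        return scenario
    return "+".join(str(s) for s in scenario)


def nested_cv_regression(table: FeatureTable, config: CVConfig,
                         scenario=None) -> PredictionResult:
    """Ridge regression under the nested protocol; returns out-of-sample R^2
    per outer fold.  ``scenario`` names the confound columns removed (fit on
    the outer training rows only)."""
    y = table.target
    if y.std() == 0:
        raise ValueError("target has zero variance")
    conf = _select_confounds(table, scenario)
    outer = RepeatedKFold(n_splits=config.outer_folds,
                          n_repeats=config.outer_repeats,
                          random_state=config.seed)
    inner = KFold(n_splits=config.inner_folds, shuffle=True,
                  random_state=config.seed)
    rows = []
    for split_idx, (tr, te) in enumerate(outer.split(table.features)):
        x_tr, x_te = table.features[tr], table.features[te]
        if conf is not None:
            remover = fit_confound_remover(x_tr, conf[tr])
            x_tr = apply_confound_remover(remover, x_tr, conf[tr])
            x_te = apply_confound_remover(remover, x_te, conf[te])
        search = GridSearchCV(
            _base_pipeline(Ridge(), config.standardize),
            {"model__alpha": list(config.ridge_alpha_grid)},
            cv=inner, scoring="r2", n_jobs=1)
        search.fit(x_tr, y[tr])
        score = r2_score(y[te], search.predict(x_te))
        rows.append({"repeat": split_idx // config.outer_folds,
                     "fold": split_idx % config.outer_folds,
                     "score": score})
    scores = pd.DataFrame(rows)
    repeat_means = scores.groupby("repeat")["score"].mean()
    return PredictionResult(scores=scores,
                            mean_score=float(scores["score"].mean()),
                            sd_score=float(repeat_means.std(ddof=1)),
                            scenario=_scenario_label(scenario),
                            model="ridge")


def binarize_by_median(values) -> np.ndarray:
    """Median split into 0 = "low" (value <= median) and 1 = "high".

    Values exactly equal to the median join the low class.  Raises when all
    values are identical (a single class is useless for classification).
    """
    v = np.asarray(values, float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    med = np.median(v)
    if np.all(v == v[0]):
        raise ValueError("all values identical: median split yields one class")
    labels = (v > med).astype(int)
    if labels.min() == labels.max():
        raise ValueError("median split produced a single class")
    return labels


def _make_classifier(model: str, config: CVConfig):
    if model == "ridge":
        return RidgeClassifier(), {"model__alpha": list(config.ridge_alpha_grid)}
    if model == "linear-svm":
        return SVC(kernel="linear"), {"model__C": list(config.svm_c_grid)}
    if model == "rbf-svm":
        return SVC(kernel="rbf"), {"model__C": list(config.svm_c_grid),
                                   "model__gamma": list(config.rbf_gamma_grid)}
    if model == "random-forest":
        return (RandomForestClassifier(random_state=0),
                {"model__max_depth": list(config.rf_max_depth_grid)})
    raise ValueError(f"unknown model {model!r}; choose from {CLASSIFIER_NAMES}")


def _decision_values(estimator, x) -> np.ndarray:
    if hasattr(estimator, "decision_function"):
        return estimator.decision_function(x)
    return estimator.predict_proba(x)[:, 1]


def nested_cv_classification(table: FeatureTable, config: CVConfig,
                             model: str = "ridge",
                             scenario=None) -> PredictionResult:
    """Binary classification under the nested protocol (stratified outer
    splits); reports accuracy and ROC AUC per outer fold."""
    y = table.target.astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("classification target must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    conf = _select_confounds(table, scenario)
    estimator, grid = _make_classifier(model, config)
    outer = RepeatedStratifiedKFold(n_splits=config.outer_folds,
                                    n_repeats=config.outer_repeats,
                                    random_state=config.seed)
    inner = KFold(n_splits=config.inner_folds, shuffle=True,
                  random_state=config.seed)
    rows = []
    for split_idx, (tr, te) in enumerate(outer.split(table.features, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("single-class outer training partition; change "
                             "the stratification seed")
        x_tr, x_te = table.features[tr], table.features[te]
        if conf is not None:
            remover = fit_confound_remover(x_tr, conf[tr])
            x_tr = apply_confound_remover(remover, x_tr, conf[tr])
            x_te = apply_confound_remover(remover, x_te, conf[te])
        search = GridSearchCV(_base_pipeline(clone(estimator), config.standardize),
                              grid, cv=inner, scoring="accuracy", n_jobs=1)
        search.fit(x_tr, y[tr])
        pred = search.predict(x_te)
        dec = _decision_values(search.best_estimator_, x_te)
        rows.append({"repeat": split_idx // config.outer_folds,
                     "fold": split_idx % config.outer_folds,
                     "score": accuracy_score(y[te], pred),
                     "auc": roc_auc_score(y[te], dec)})
    scores = pd.DataFrame(rows)
    repeat_means = scores.groupby("repeat")[["score", "auc"]].mean()
    return PredictionResult(scores=scores,
                            mean_score=float(scores["score"].mean()),
                            sd_score=float(repeat_means["score"].std(ddof=1)),
                            scenario=_scenario_label(scenario),
                            model=model,
                            mean_auc=float(scores["auc"].mean()),
                            sd_auc=float(repeat_means["auc"].std(ddof=1)))


def score_derivative(scores: Dict[int, float] | pd.Series) -> pd.Series:
    """First differences of prediction scores over consecutive n_align values.

    Returns a Series indexed by the upper n_align of each consecutive pair.
    Raises if the n_align index has gaps.
    """
    if isinstance(scores, dict):
        scores = pd.Series(scores)
    idx = np.asarray(scores.index, int)
    order = np.argsort(idx)
    idx, vals = idx[order], scores.to_numpy(float)[order]
    if idx.size < 2:
        raise ValueError("need at least 2 consecutive n_align values")
    if np.any(np.diff(idx) != 1):
        raise ValueError("n_align index has gaps; derivative undefined")
    return pd.Series(np.diff(vals), index=idx[1:])
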
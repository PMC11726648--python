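"""Progression classification from normative patch z-scores.

For each progression outcome (extremity, total motor, cognitive) and horizon
(1 or 3 years), an SVM predicts progressor vs. non-progressor from baseline
per-patch z-scores.  Two feature modes are compared: ``restricted_roi``
feeds the pre-selected domain-specific patch set unchanged; ``wholebrain_selected``
filters all patches down to the same number (default 79) by absolute
two-sample t-statistic on the training split only.  Hyperparameters (C,
gamma for the RBF kernel) are tuned by stratified fivefold cross-validation
on the 80% training split; accuracy is reported on the held-out 20%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .progression import MEASURES, HORIZONS, label_progressors
from .roi import PatchSet

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0)

FEATURE_MODES = ("restricted_roi", "wholebrain_selected")


class SplitError(ValueError):
    """Raised when a train/test split leaves a class unrepresented."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Settings of one SVM experiment cell."""

    test_fraction: float = 0.2
    n_features: int = 79
    kernel: str = "rbf"
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    cv_folds: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be nonempty")
        if any(c <= 0 for c in self.c_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("C and gamma must be positive")


def split_train_test(subject_ids: Sequence[str], labels: np.ndarray,
                     config: ClassifierConfig) -> tuple[list[str], list[str]]:
    """Deterministic 80/20 split; test size = round(test_fraction * n).

    With ``stratified=True`` the per-class test counts follow a
    largest-remainder apportionment of the overall test size, keeping class
    proportions within one subject of the population rates.
    """
    ids = np.asarray(subject_ids)
    y = np.asarray(labels)
    n = ids.size
    if n < 10:
        raise SplitError("need at least 10 subjects to split")
    classes = np.unique(y)
    if classes.size < 2:
        raise SplitError("both classes must be present before splitting")
    rng = np.random.default_rng(config.seed)
    n_test = int(round(config.test_fraction * n))
    n_test = min(max(n_test, 1), n - 2)

    if config.stratified:
        quotas = {}
        exact = {c: config.test_fraction * (y == c).sum() for c in classes}
        base = {c: int(np.floor(exact[c])) for c in classes}
        remainder = n_test - sum(base.values())
        order = sorted(classes, key=lambda c: exact[c] - base[c], reverse=True)
        for c in classes:
            quotas[c] = base[c]
        for c in order[:remainder]:
            quotas[c] += 1
        test_idx: list[int] = []
        for c in classes:
            members = np.flatnonzero(y == c)
            picked = rng.permutation(members)[: quotas[c]]
            test_idx.extend(picked.tolist())
        test_idx = sorted(test_idx)
    else:
        test_idx = sorted(rng.permutation(n)[:n_test].tolist())

    test_mask = np.zeros(n, dtype=bool)
    test_mask[test_idx] = True
    train_ids = ids[~test_mask].tolist()
    test_ids = ids[test_mask].tolist()
    if np.unique(y[~test_mask]).size < 2:
        raise SplitError(
            "a class is absent from the training split; re-seed or enable stratification"
        )
    return train_ids, test_ids


def select_features(train_features: np.ndarray, train_labels: np.ndarray,
                    k: int = 79) -> np.ndarray:
    """Top-k features by absolute two-sample t-statistic (train data only).

    Zero-variance features have an undefined t and rank last; ties break
    toward the lower feature index.  Returns sorted selected indices.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds {X.shape[1]} available features")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("feature selection needs exactly two classes")
    a, b = X[y == classes[0]], X[y == classes[1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = sps.ttest_ind(a, b, axis=0, equal_var=True)
    score = np.abs(t)
    score[~np.isfinite(score)] = -np.inf  # undefined t ranks last
    order = np.lexsort((np.arange(X.shape[1]), -score))
    return np.sort(order[:k])


def tune_and_train(train_features: np.ndarray, train_labels: np.ndarray,
                   config: ClassifierConfig) -> tuple[SVC, dict[str, float], float]:
    """Grid-search (C, gamma) by stratified fivefold CV, refit on all training data.

    Ties in mean CV accuracy break toward the smallest C, then the smallest
    gamma (grids are scanned in ascending order with a strict improvement
    rule).
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                         random_state=config.seed)
    best: tuple[float, float, float] | None = None  # (cv_acc, C, gamma)
    gamma_grid = sorted(config.gamma_grid) if config.kernel == "rbf" else [None]
    for c in sorted(config.c_grid):
        for gamma in gamma_grid:
            svc = _make_svc(config.kernel, c, gamma)
            acc = float(cross_val_score(svc, X, y, cv=cv, scoring="accuracy").mean())
            if best is None or acc > best[0]:
                best = (acc, c, gamma)
    cv_acc, c, gamma = best
    model = _make_svc(config.kernel, c, gamma).fit(X, y)
    params = {"C": c}
    if gamma is not None:
        params["gamma"] = gamma
    return model, params, cv_acc


def _make_svc(kernel: str, c: float, gamma: float | None) -> SVC:
    if kernel == "rbf":
        return SVC(kernel="rbf", C=c, gamma=gamma)
    return SVC(kernel=kernel, C=c)


def evaluate(model: SVC, test_features: np.ndarray,
             test_labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Held-out accuracy (fraction of correctly classified cases) + predictions."""
    X = np.asarray(test_features, dtype=float)
    y = np.asarray(test_labels)
    if X.shape[0] == 0:
        raise ValueError("empty test set")
    pred = model.predict(X)
    return float((pred == y).mean()), pred


class ProgressionClassifier(ClassifierMixin, BaseEstimator):
    """SVM progression classifier with built-in feature selection and tuning.

    Parameters
    ----------
    mode : {"restricted_roi", "wholebrain_selected"}
        Restricted mode uses ``patch_set`` unchanged as the features;
        whole-brain mode selects ``n_features`` patches by absolute
        t-statistic on the training data.
    patch_set : PatchSet, optional
        Required in restricted mode; its indices address columns of X.
    n_features : int
        Number of patches fed to the SVM (restricted mode: the ROI size).
    c_grid, gamma_grid : tuples of float
        RBF hyperparameter search grids.
    cv_folds : int
        Stratified CV folds for tuning.
    kernel : str
        "rbf" (default) or "linear".
    random_state : int
        Seed for CV fold shuffling.

    Attributes (after fit)
    ----------------------
    selected_features_ : ndarray of sorted selected column indices
    best_params_ : dict of tuned hyperparameters
    cv_accuracy_ : mean CV accuracy of the winning grid point
    model_ : the refitted SVC
    """

    def __init__(self, mode: str = "wholebrain_selected",
                 patch_set: PatchSet | None = None, n_features: int = 79,
                 c_grid: tuple[float, ...] = DEFAULT_C_GRID,
                 gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
                 cv_folds: int = 5, kernel: str = "rbf", random_state: int = 0):
        self.mode = mode
        self.patch_set = patch_set
        self.n_features = n_features
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.cv_folds = cv_folds
        self.kernel = kernel
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.mode not in FEATURE_MODES:
            raise ValueError(f"mode must be one of {FEATURE_MODES}")
        if self.mode == "restricted_roi":
            if self.patch_set is None:
                raise ValueError("restricted_roi mode requires patch_set")
            self.patch_set.validate_range(X.shape[1])
            self.selected_features_ = self.patch_set.as_array()
        else:
            self.selected_features_ = select_features(X, y, k=self.n_features)
        config = ClassifierConfig(n_features=self.n_features, kernel=self.kernel,
                                  c_grid=tuple(self.c_grid),
                                  gamma_grid=tuple(self.gamma_grid),
                                  cv_folds=self.cv_folds, seed=self.random_state)
        self.model_, self.best_params_, self.cv_accuracy_ = tune_and_train(
            X[:, self.selected_features_], y, config)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        return self.model_.predict(X[:, self.selected_features_])


@dataclass
class ClassifierReport:
    """One experiment cell: split, selected patches, tuning, and accuracy."""

    outcome: str
    horizon: str
    feature_mode: str
    train_ids: list[str]
    test_ids: list[str]
    selected_patches: list[int]
    best_hyperparameters: dict[str, float]
    cv_accuracy: float
    test_accuracy: float
    predictions: list[dict]
    seed: int

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "horizon": self.horizon,
            "feature_mode": self.feature_mode,
            "n_train": len(self.train_ids),
            "n_test": len(self.test_ids),
            "train_ids": self.train_ids,
            "test_ids": self.test_ids,
            "selected_patches": self.selected_patches,
            "best_hyperparameters": self.best_hyperparameters,
            "cv_accuracy": self.cv_accuracy,
            "test_accuracy": self.test_accuracy,
            "predictions": self.predictions,
            "seed": self.seed,
        }


def run_experiment_cell(z_matrix: pd.DataFrame, labels: pd.DataFrame,
                        mode: str, roi: PatchSet,
                        config: ClassifierConfig) -> ClassifierReport:
    """One (feature mode x outcome x horizon) cell on baseline z-scores."""
    merged = labels.merge(z_matrix, on="subject_id", how="inner")
    ids = merged["subject_id"].tolist()
    y = merged["progressor"].to_numpy(dtype=bool)
    patch_cols = [c for c in z_matrix.columns if c != "subject_id"]
    X = merged[patch_cols].to_numpy(dtype=float)

    train_ids, test_ids = split_train_test(ids, y, config)
    pos = {sid: i for i, sid in enumerate(ids)}
    tr = np.array([pos[s] for s in train_ids])
    te = np.array([pos[s] for s in test_ids])

    clf = ProgressionClassifier(
        mode=mode, patch_set=roi if mode == "restricted_roi" else None,
        n_features=config.n_features, c_grid=config.c_grid,
        gamma_grid=config.gamma_grid, cv_folds=config.cv_folds,
        kernel=config.kernel, random_state=config.seed,
    ).fit(X[tr], y[tr])
    acc, pred = evaluate(clf.model_, X[te][:, clf.selected_features_], y[te])
    predictions = [
        {"subject_id": sid, "predicted": bool(p), "observed": bool(o)}
        for sid, p, o in zip(test_ids, pred, y[te])
    ]
    return ClassifierReport(
        outcome=str(labels["measure"].iloc[0]),
        horizon=str(labels["horizon"].iloc[0]),
        feature_mode=mode,
        train_ids=train_ids, test_ids=test_ids,
        selected_patches=[int(i) for i in clf.selected_features_],
        best_hyperparameters=clf.best_params_,
        cv_accuracy=clf.cv_accuracy_, test_accuracy=acc,
        predictions=predictions, seed=config.seed,
    )


def run_full_experiment(z_matrix: pd.DataFrame, clinical: pd.DataFrame,
                        roi: PatchSet,
                        config: ClassifierConfig) -> list[ClassifierReport]:
    """All 12 cells: {restricted, whole-brain} x {3 outcomes} x {Y1, Y3}."""
    reports = []
    for horizon in HORIZONS:
        for measure in MEASURES:
            labels = label_progressors(clinical, measure, horizon)
            for mode in FEATURE_MODES:
                reports.append(run_experiment_cell(z_matrix, labels, mode, roi, config))
    return reports


def summary_table(reports: Sequence[ClassifierReport]) -> pd.DataFrame:
    """Accuracy summary mirroring a feature-mode x outcome x horizon grid."""
    rows = [(r.feature_mode, r.outcome, r.horizon, r.cv_accuracy, r.test_accuracy,
             len(r.train_ids), len(r.test_ids)) for r in reports]
    return pd.DataFrame(rows, columns=["feature_mode", "outcome", "horizon",
                                       "cv_accuracy", "test_accuracy",
                                       "n_train", "n_test"])
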
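"""SVM classification of the two groups from EEG features.

Features are z-scored (statistics fitted on training rows only), a
support-vector machine with a linear or Gaussian-RBF kernel is tuned by
grid search, and performance is estimated by *nested* cross-validation:
a leave-one-out outer loop for the generalization estimate, a stratified
5-fold inner loop for hyperparameter selection, so the held-out subject
never influences scaling or tuning.  Accuracy is the fraction of correct
out-of-fold predictions; the ROC/AUC is computed from the pooled
out-of-fold decision values (single-subject outer folds have no AUC of
their own).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_selection import VarianceThreshold
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

from .features import FEATURE_SETS

__all__ = [
    "ClassifierConfig",
    "zscore_features",
    "NestedSVMClassifier",
    "nested_cv_svm",
    "roc_auc",
    "evaluate_feature_sets",
]

_DEFAULT_C = tuple(np.logspace(-2, 2, 5))
_DEFAULT_GAMMA = tuple(np.logspace(-3, 1, 5))


@dataclass(frozen=True)
class ClassifierConfig:
    """Kernel and search-grid settings for nested-CV SVM evaluation."""

    kernels: tuple[str, ...] = ("linear", "rbf")
    C_grid: tuple[float, ...] = _DEFAULT_C
    gamma_grid: tuple[float, ...] = _DEFAULT_GAMMA
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be at least 2")
        bad = set(self.kernels) - {"linear", "rbf"}
        if bad:
            raise ValueError(f"unsupported kernels: {sorted(bad)}")


def zscore_features(train_rows: np.ndarray, apply_rows: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize with statistics fitted on the training rows only.

    Constant (zero-variance) features are dropped from both sets with a
    warning.  Returns ``(train_z, apply_z, kept_column_indices)``.
    """
    train = np.asarray(train_rows, dtype=float)
    apply_ = np.asarray(apply_rows, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    sd = train.std(axis=0, ddof=0)
    keep = np.flatnonzero(sd > 0)
    if keep.size < train.shape[1]:
        warnings.warn(f"dropping {train.shape[1] - keep.size} constant feature(s)",
                      stacklevel=2)
    mu = train[:, keep].mean(axis=0)
    s = sd[keep]
    return (train[:, keep] - mu) / s, (apply_[:, keep] - mu) / s, keep


def _make_pipeline(kernel: str, C: float, gamma) -> Pipeline:
    # balanced class weights: the leave-one-out outer loop unbalances every
    # training set by one subject, which otherwise biases the pooled
    # decision values against the held-out subject's class
    return Pipeline([
        ("variance", VarianceThreshold(0.0)),
        ("scale", StandardScaler()),
        ("svm", SVC(kernel=kernel, C=C, gamma=gamma, class_weight="balanced")),
    ])


class NestedSVMClassifier(BaseEstimator, ClassifierMixin):
    """SVM with grid-searched hyperparameters and nested-CV evaluation.

    ``fit`` does two things: it runs the leave-one-out outer loop (inner
    stratified k-fold grid search per fold) to produce unbiased
    out-of-fold performance estimates, and it refits a final model on all
    rows (tuned by the same inner search) for subsequent ``predict`` /
    ``decision_function`` calls.

    Parameters
    ----------
    kernel : {"linear", "rbf"}
    C_grid, gamma_grid : sequences of positive floats
        Grid-search candidates (``gamma_grid`` is ignored for the linear
        kernel).
    inner_folds : int, default 5
    random_state : int, default 0
        Seeds the inner-fold shuffling; results are reproducible.

    Attributes
    ----------
    accuracy_ : float
        Mean out-of-fold correctness over the outer loop.
    auc_ : float
        ROC AUC of the pooled out-of-fold decision values.
    oof_decision_, oof_pred_ : ndarray
        Out-of-fold decision values and predictions, one per subject.
    fold_params_ : list of dict
        Hyperparameters chosen in each outer fold.
    best_estimator_ : sklearn Pipeline
        Final model refit on all data.
    """

    def __init__(self, kernel: str = "linear", C_grid=_DEFAULT_C,
                 gamma_grid=_DEFAULT_GAMMA, inner_folds: int = 5,
                 random_state: int = 0):
        self.kernel = kernel
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.inner_folds = inner_folds
        self.random_state = random_state

    def _param_grid(self) -> dict:
        grid = {"svm__C": list(self.C_grid)}
        if self.kernel == "rbf":
            grid["svm__gamma"] = list(self.gamma_grid)
        return grid

    def _search(self, X, y) -> GridSearchCV:
        n_min = min(np.bincount(y))
        folds = max(2, min(self.inner_folds, n_min))
        inner = StratifiedKFold(n_splits=folds, shuffle=True,
                                random_state=self.random_state)
        gs = GridSearchCV(_make_pipeline(self.kernel, 1.0, "scale"),
                          self._param_grid(), cv=inner, scoring="accuracy",
                          n_jobs=None, refit=True)
        gs.fit(X, y)
        return gs

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError("exactly two classes required")
        if min(np.bincount(y_enc)) < 2:
            raise ValueError("need at least 2 subjects per class")
        n = X.shape[0]
        oof_dec = np.full(n, np.nan)
        oof_pred = np.full(n, -1)
        fold_params: list[dict] = []
        skipped = []
        for i in range(n):
            train = np.delete(np.arange(n), i)
            ytr = y_enc[train]
            if np.unique(ytr).size < 2:
                skipped.append(i)
                fold_params.append({})
                continue
            gs = self._search(X[train], ytr)
            fold_params.append(dict(gs.best_params_))
            oof_dec[i] = float(gs.decision_function(X[i:i + 1])[0])
            oof_pred[i] = int(gs.predict(X[i:i + 1])[0])
        valid = oof_pred >= 0
        self.oof_decision_ = oof_dec
        self.oof_pred_ = oof_pred
        self.fold_params_ = fold_params
        self.skipped_folds_ = skipped
        self.accuracy_ = float((oof_pred[valid] == y_enc[valid]).mean())
        self.auc_ = float(roc_auc_score(y_enc[valid], oof_dec[valid]))
        final = self._search(X, y_enc)
        self.best_estimator_ = final.best_estimator_
        self.best_params_ = dict(final.best_params_)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.decision_function(X)

    def predict(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.classes_[self.best_estimator_.predict(X)]


def roc_auc(labels: np.ndarray, scores: np.ndarray
            ) -> tuple[np.ndarray, float]:
    """ROC points and AUC from binary labels and continuous scores.

    The AUC equals the probability that a positive's score exceeds a
    negative's, ties counted one half; the returned curve is the standard
    (FPR, TPR) staircase whose trapezoidal integral agrees.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("both classes must be present")
    y = (labels == classes[1]).astype(int)
    fpr, tpr, _ = roc_curve(y, scores)
    return np.column_stack([fpr, tpr]), float(roc_auc_score(y, scores))


def nested_cv_svm(table: pd.DataFrame, feature_set, config: ClassifierConfig
                  ) -> pd.DataFrame:
    """Nested-CV evaluation of one feature set under each configured kernel.

    ``feature_set`` is a named set from :data:`eegdyn.features.FEATURE_SETS`
    or an explicit list of column names; ``table`` needs a ``group``
    column.  Returns one row per kernel with accuracy, AUC and the chosen
    hyperparameters, plus the pooled decision values.
    """
    cols = list(FEATURE_SETS[feature_set]) if isinstance(feature_set, str) \
        else list(feature_set)
    X = table[cols].to_numpy(dtype=float)
    y = table["group"].to_numpy()
    rows = []
    for kernel in config.kernels:
        clf = NestedSVMClassifier(kernel=kernel, C_grid=config.C_grid,
                                  gamma_grid=config.gamma_grid,
                                  inner_folds=config.inner_folds,
                                  random_state=config.seed).fit(X, y)
        rows.append({"feature_set": feature_set if isinstance(feature_set, str)
                     else "+".join(cols),
                     "kernel": kernel, "accuracy": clf.accuracy_,
                     "auc": clf.auc_, "n_features": len(cols),
                     "decision_values": clf.oof_decision_.tolist(),
                     "final_params": clf.best_params_})
    return pd.DataFrame(rows)


def evaluate_feature_sets(table: pd.DataFrame,
                          feature_sets=("microstate", "omega", "combined"),
                          config: ClassifierConfig | None = None) -> pd.DataFrame:
    """Compare the named feature sets under nested-CV SVM."""
    config = config or ClassifierConfig()
    return pd.concat([nested_cv_svm(table, fs, config) for fs in feature_sets],
                     ignore_index=True)
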
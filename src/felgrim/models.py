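"""Gradient-boosted prediction of FGS scores from geometric descriptors.

Three task families mirror how FGS labels are formed:

* binary — painful / non-painful from the aggregated total score at the
  analgesia cut-off, with the positive class weighted by the
  negative/positive count ratio (``scale_pos_weight``);
* regression — the total FGS score ratio in [0, 1];
* ordinal — one 0/1/2 model per action unit (3-class softmax trees, errors
  reported as MSE between predicted and true class integers).

All estimators follow the scikit-learn protocol (``fit`` / ``predict`` /
``get_params``), run an exhaustive hyperparameter grid search with shuffled
5-fold cross-validation, and are deterministic under a fixed ``random_state``.
Feature selection is provided as recursive feature elimination (backward,
gain-importance, subset size chosen by 4-fold CV) and a Boruta procedure on
exact tree-SHAP attributions with shuffled shadow features.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import xgboost as xgb
from scipy.stats import binomtest
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "HyperGrid",
    "DEFAULT_GRID",
    "FGSBinaryClassifier",
    "FGSRegressor",
    "FGSOrdinalClassifier",
    "RFESelector",
    "BorutaShapSelector",
    "StandardizedPCA",
    "compute_scale_pos_weight",
    "auroc",
    "mse",
    "rfe_select",
    "boruta_shap_select",
    "pca_project",
    "shuffled_split",
]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_scale_pos_weight(labels) -> float:
    """Positive-class weight for imbalanced boosting: n_negative / n_positive."""
    y = np.asarray(labels)
    pos = int(np.sum(y == 1))
    neg = int(np.sum(y == 0))
    if pos == 0 or neg == 0:
        raise ValueError("scale_pos_weight needs both classes present "
                         f"(got {pos} positives, {neg} negatives)")
    return neg / pos


def auroc(scores, labels) -> float:
    """Area under the ROC curve as pairwise concordance.

    Probability that a randomly chosen positive outscores a randomly chosen
    negative, ties counted 1/2 — identical to the trapezoidal ROC area.
    Computed from midranks so it is exact for any tie pattern.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined with a single class")
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), float)
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0  # midrank, 1-based
        i = j + 1
    rank_sum_pos = ranks[y == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def mse(pred, truth) -> float:
    """Mean squared error."""
    p = np.asarray(pred, float)
    t = np.asarray(truth, float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    return float(np.mean((p - t) ** 2))


def shuffled_split(n: int, test_size=100, seed: int = 0):
    """Seeded shuffled train/test index split (test_size int or fraction)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = int(round(test_size * n)) if isinstance(test_size, float) else int(test_size)
    if not 0 < k < n:
        raise ValueError(f"test_size {test_size} invalid for n={n}")
    return perm[k:], perm[:k]


# ---------------------------------------------------------------------------
# Hyperparameter grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperGrid:
    """Candidate values for the five tuned boosting hyperparameters
    (tree count, learning rate, L1 penalty, depth, row/column subsampling)."""

    n_estimators: tuple = (100, 300)
    learning_rate: tuple = (0.05, 0.1, 0.3)
    reg_alpha: tuple = (0.0, 0.5, 1.0)
    max_depth: tuple = (3, 5)
    subsample: tuple = (0.8, 1.0)
    colsample_bytree: tuple = (0.8, 1.0)

    def __post_init__(self):
        for name in ("n_estimators", "learning_rate", "reg_alpha", "max_depth",
                     "subsample", "colsample_bytree"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"{name} candidate list is empty")
        if any(d < 1 for d in self.max_depth):
            raise ValueError("max_depth values must be >= 1")
        if any(r <= 0 for r in self.learning_rate):
            raise ValueError("learning rates must be > 0")
        for name in ("subsample", "colsample_bytree"):
            if any(not 0 < v <= 1 for v in getattr(self, name)):
                raise ValueError(f"{name} values must lie in (0, 1]")

    def combinations(self):
        keys = ("n_estimators", "learning_rate", "reg_alpha", "max_depth",
                "subsample", "colsample_bytree")
        for vals in itertools.product(*(getattr(self, k) for k in keys)):
            yield dict(zip(keys, vals))


DEFAULT_GRID = HyperGrid()

_XGB_FIXED = dict(tree_method="hist", n_jobs=1, verbosity=0)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class _GridSearchedBooster(BaseEstimator):
    """Shared grid-search-with-CV machinery for the three task estimators."""

    _task = None  # "binary" | "regression" | "ordinal"

    def __init__(self, grid: HyperGrid = DEFAULT_GRID, n_splits: int = 5,
                 random_state: int = 0):
        self.grid = grid
        self.n_splits = n_splits
        self.random_state = random_state

    # -- task hooks ---------------------------------------------------------
    def _make_model(self, params, y_train):
        raise NotImplementedError

    def _fold_score(self, model, X_val, y_val) -> float:
        raise NotImplementedError

    def _check_y(self, y):
        return np.asarray(y)

    # -- sklearn protocol ---------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, float)
        y = self._check_y(y)
        if X.shape[0] != len(y):
            raise ValueError("X and y are misaligned")
        if X.shape[0] < 2 * self.n_splits:
            raise ValueError(f"need >= {2 * self.n_splits} samples for "
                             f"{self.n_splits}-fold CV")
        folds = self._folds(X, y)
        results = []
        for params in self.grid.combinations():
            scores = []
            for tr, va in folds:
                model = self._make_model(params, y[tr])
                model.fit(X[tr], y[tr])
                scores.append(self._fold_score(model, X[va], y[va]))
            results.append((params, scores))
        best_i = int(np.argmax([np.mean(s) for _, s in results]))
        self.best_params_, self.cv_scores_ = results[best_i]
        self.cv_results_ = [
            {"params": p, "mean_score": float(np.mean(s)), "fold_scores": list(s)}
            for p, s in results]
        self.model_ = self._make_model(self.best_params_, y)
        self.model_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def _folds(self, X, y):
        cv = KFold(n_splits=self.n_splits, shuffle=True,
                   random_state=self.random_state)
        folds = list(cv.split(X))
        if self._task == "binary":
            # a single-class training fold breaks the positive-class weight:
            # fall back to a stratified split
            if any(len(np.unique(y[tr])) < 2 for tr, _ in folds):
                cv = StratifiedKFold(n_splits=self.n_splits, shuffle=True,
                                     random_state=self.random_state)
                folds = list(cv.split(X, y))
        return folds

    def predict(self, X):
        return self.model_.predict(np.asarray(X, float))


class FGSBinaryClassifier(_GridSearchedBooster):
    """Painful / non-painful classifier (grid-searched boosted trees).

    Cross-validation scores accuracy; every fold model and the final refit
    receive ``scale_pos_weight`` computed on its own training labels.
    """

    _task = "binary"

    def _check_y(self, y):
        y = np.asarray(y)
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("binary labels must be 0/1")
        return y.astype(int)

    def _make_model(self, params, y_train):
        return xgb.XGBClassifier(
            **params, **_XGB_FIXED, random_state=self.random_state,
            scale_pos_weight=compute_scale_pos_weight(y_train),
            eval_metric="logloss")

    def _fold_score(self, model, X_val, y_val):
        return float(np.mean(model.predict(X_val) == y_val))

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X, float))

    def decision_scores(self, X):
        """Positive-class probability, the score used for AUROC."""
        return self.predict_proba(X)[:, 1]

    def scale_pos_weight_(self):
        return self.model_.get_params()["scale_pos_weight"]


class FGSRegressor(_GridSearchedBooster):
    """Total FGS score (ratio 0-1) regressor; CV scores negative MSE."""

    _task = "regression"

    def _make_model(self, params, y_train):
        return xgb.XGBRegressor(**params, **_XGB_FIXED,
                                random_state=self.random_state)

    def _fold_score(self, model, X_val, y_val):
        return -mse(model.predict(X_val), y_val)


class FGSOrdinalClassifier(_GridSearchedBooster):
    """Per-AU ordinal 0/1/2 model (3-class softmax trees).

    Following the reporting convention for ordinal scores, CV and evaluation
    use MSE between the predicted and true class integers, so a two-level
    miss costs four times a one-level miss.
    """

    _task = "ordinal"

    def _check_y(self, y):
        y = np.asarray(y)
        if not set(np.unique(y)) <= {0, 1, 2}:
            raise ValueError("ordinal labels must be 0, 1 or 2")
        return y.astype(int)

    def _make_model(self, params, y_train):
        return xgb.XGBClassifier(**params, **_XGB_FIXED, num_class=3,
                                 objective="multi:softmax",
                                 random_state=self.random_state)

    def _fold_score(self, model, X_val, y_val):
        return -mse(model.predict(X_val), y_val)

    def predict(self, X):
        pred = super().predict(X)
        return np.asarray(pred, int)


def _task_estimator(task: str, seed: int, grid: HyperGrid | None = None):
    grid = grid or DEFAULT_GRID
    cls = {"binary": FGSBinaryClassifier, "regression": FGSRegressor,
           "ordinal": FGSOrdinalClassifier}.get(task)
    if cls is None:
        raise ValueError(f"unknown task {task!r}")
    return cls(grid=grid, random_state=seed)


def _selection_model(task: str, y, seed: int, n_estimators: int = 100,
                     max_depth: int = 3, learning_rate: float = 0.1):
    """Fixed mid-grid booster used inside feature-selection loops."""
    common = dict(n_estimators=n_estimators, max_depth=max_depth,
                  learning_rate=learning_rate, **_XGB_FIXED, random_state=seed)
    if task == "binary":
        return xgb.XGBClassifier(
            **common, scale_pos_weight=compute_scale_pos_weight(y),
            eval_metric="logloss")
    if task == "regression":
        return xgb.XGBRegressor(**common)
    if task == "ordinal":
        return xgb.XGBClassifier(**common, num_class=3, objective="multi:softmax")
    raise ValueError(f"unknown task {task!r}")


def _selection_score(task, model, X_val, y_val):
    # binary subset selection scores negative log-loss rather than accuracy:
    # a continuous criterion discriminates nested feature subsets that tie
    # on the quantised accuracy scale
    if task == "binary":
        p = np.clip(model.predict_proba(X_val)[:, 1], 1e-12, 1 - 1e-12)
        return float(np.mean(y_val * np.log(p) + (1 - y_val) * np.log(1 - p)))
    return -mse(model.predict(X_val), y_val)


# ---------------------------------------------------------------------------
# Recursive feature elimination
# ---------------------------------------------------------------------------

class RFESelector(BaseEstimator):
    """Backward greedy feature elimination with cross-validated subset choice.

    At each step the boosted model is scored by shuffled ``n_splits``-fold CV
    on the surviving features, then refit on all rows and the feature with
    the lowest gain importance is dropped.  The surviving subset with the
    best CV score is kept; ties resolve to the smallest tied subset
    (parsimony).
    """

    def __init__(self, task: str = "binary", n_splits: int = 4,
                 random_state: int = 0):
        self.task = task
        self.n_splits = n_splits
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        p = X.shape[1]
        if p < 1:
            raise ValueError("need at least one feature")
        cv = KFold(n_splits=self.n_splits, shuffle=True,
                   random_state=self.random_state)
        folds = list(cv.split(X))
        surviving = list(range(p))
        self.path_ = []
        while surviving:
            cols = np.array(surviving)
            scores = []
            for tr, va in folds:
                m = _selection_model(self.task, y[tr], self.random_state)
                m.fit(X[np.ix_(tr, cols)], y[tr])
                scores.append(_selection_score(self.task, m,
                                               X[np.ix_(va, cols)], y[va]))
            self.path_.append((list(surviving), float(np.mean(scores))))
            if len(surviving) == 1:
                break
            full = _selection_model(self.task, y, self.random_state)
            full.fit(X[:, cols], y)
            booster = full.get_booster()
            gains = booster.get_score(importance_type="gain")
            imp = np.array([gains.get(f"f{j}", 0.0) for j in range(len(cols))])
            worst = int(np.argmin(imp))
            surviving.pop(worst)
        best_score = max(s for _, s in self.path_)
        # smallest subset attaining the best score (path_ shrinks along it)
        best = max(i for i, (_, s) in enumerate(self.path_) if s == best_score)
        self.selected_, self.best_score_ = self.path_[best]
        self.support_ = np.zeros(p, bool)
        self.support_[self.selected_] = True
        self.n_features_in_ = p
        return self

    def transform(self, X):
        return np.asarray(X, float)[:, self.support_]


def rfe_select(X, y, task: str = "binary", seed: int = 0,
               n_splits: int = 4) -> list:
    """Indices of the features surviving recursive elimination (see
    :class:`RFESelector`)."""
    sel = RFESelector(task=task, n_splits=n_splits, random_state=seed).fit(X, y)
    return sel.selected_


# ---------------------------------------------------------------------------
# Boruta on tree-SHAP attributions
# ---------------------------------------------------------------------------

class BorutaShapSelector(BaseEstimator):
    """Boruta relevance test on exact tree-SHAP feature attributions.

    Each trial appends an independently shuffled shadow copy of every
    feature, fits the boosted model on the widened matrix, computes each
    column's mean absolute SHAP attribution (exact TreeSHAP for tree
    ensembles), z-scores the attributions within the trial, and records a
    hit for every real feature whose z-score exceeds the maximum shadow
    z-score.  A feature is relevant when its hit count is significantly
    above the 50% chance level (one-sided binomial test at ``alpha``).
    """

    def __init__(self, task: str = "binary", n_trials: int = 20,
                 alpha: float = 0.05, random_state: int = 0):
        self.task = task
        self.n_trials = n_trials
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        n, p = X.shape
        if p < 2:
            raise ValueError("need at least two features")
        if self.n_trials < 5:
            raise ValueError("need at least five trials")
        rng = np.random.default_rng(self.random_state)
        hits = np.zeros(p, int)
        for trial in range(self.n_trials):
            shadow = np.column_stack([rng.permutation(X[:, j]) for j in range(p)])
            Xw = np.hstack([X, shadow])
            m = _selection_model(self.task, y, self.random_state + trial)
            m.fit(Xw, y)
            contrib = m.get_booster().predict(xgb.DMatrix(Xw), pred_contribs=True)
            if contrib.ndim == 3:  # multiclass: (n, class, feature+bias)
                imp = np.abs(contrib[:, :, :-1]).mean(axis=(0, 1))
            else:
                imp = np.abs(contrib[:, :-1]).mean(axis=0)
            sd = imp.std()
            z = (imp - imp.mean()) / (sd if sd > 0 else 1.0)
            thresh = z[p:].max()
            hits += (z[:p] > thresh).astype(int)
        self.hits_ = hits
        self.pvalues_ = np.array([
            binomtest(int(h), self.n_trials, 0.5, alternative="greater").pvalue
            for h in hits])
        self.support_ = self.pvalues_ < self.alpha
        self.selected_ = list(np.flatnonzero(self.support_))
        self.n_features_in_ = p
        return self

    def transform(self, X):
        return np.asarray(X, float)[:, self.support_]


def boruta_shap_select(X, y, task: str = "binary", n_trials: int = 20,
                       seed: int = 0, alpha: float = 0.05) -> list:
    """Indices of features accepted by the Boruta/tree-SHAP procedure."""
    sel = BorutaShapSelector(task=task, n_trials=n_trials, alpha=alpha,
                             random_state=seed).fit(X, y)
    return sel.selected_


# ---------------------------------------------------------------------------
# PCA visualisation of the descriptor covariance structure
# ---------------------------------------------------------------------------

class StandardizedPCA(BaseEstimator):
    """PCA on z-scored features; zero-variance features are dropped with a
    warning (they carry no covariance information)."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.shape[0] <= self.n_components:
            raise ValueError("need more rows than components")
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} zero-variance "
                          "feature(s) before PCA")
        self.keep_ = keep
        self.mean_ = X[:, keep].mean(axis=0)
        self.sd_ = sd[keep]
        Z = (X[:, keep] - self.mean_) / self.sd_
        self.pca_ = PCA(n_components=min(self.n_components, Z.shape[1]),
                        svd_solver="full").fit(Z)
        self.components_ = self.pca_.components_
        self.explained_variance_ratio_ = self.pca_.explained_variance_ratio_
        return self

    def transform(self, X):
        X = np.asarray(X, float)
        Z = (X[:, self.keep_] - self.mean_) / self.sd_
        return self.pca_.transform(Z)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)

    def inverse_standardized(self, coords):
        """Reconstruct the standardized data from projected coordinates."""
        return np.asarray(coords, float) @ self.components_ + self.pca_.mean_


def pca_project(X, n_components: int = 2):
    """(projected coordinates, explained-variance ratios) of z-scored *X*."""
    p = StandardizedPCA(n_components=n_components).fit(X)
    return p.transform(X), p.explained_variance_ratio_
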
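"""Group classification from regional NH features.

ROC analysis with Youden-index cut-offs per single feature, and
leave-one-out RBF-SVM with (C, gamma) grid search over every nonempty
feature subset — the layout of a diagnostic-accuracy table. Patients are
the positive class throughout; ROC scores are auto-oriented so reported
AUCs are >= 0.5 (with the flip recorded), since patients may sit lower than
controls on a given NH feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

__all__ = [
    "ROCResult",
    "SVMResult",
    "roc_with_youden",
    "LooGridSVC",
    "svm_loo_accuracy",
    "subset_search",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
]

#: Canonical soft-margin / kernel-width grids: C = 2^-5 .. 2^15, gamma = 2^-15 .. 2^3.
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass
class ROCResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden: float
    accuracy: float  # fraction correct at the Youden cut-off
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    flipped: bool  # True when the score was negated to orient AUC >= 0.5

    @property
    def curve(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


def _trapezoid_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def roc_with_youden(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve, AUC and the Youden-maximizing cut-off.

    ``labels`` mark patients as 1 (positive class). The AUC is the
    trapezoidal integral over all distinct thresholds, which equals the
    Mann-Whitney concordance probability with ties counted half. If the raw
    AUC falls below 0.5 the score is negated first and the flip recorded.
    Youden ties resolve toward higher sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    flipped = False
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = _trapezoid_auc(fpr, tpr)
    if auc < 0.5:
        flipped = True
        scores = -scores
        fpr, tpr, thr = roc_curve(labels, scores)
        auc = _trapezoid_auc(fpr, tpr)
    j = tpr - fpr
    best = max(range(len(j)), key=lambda i: (j[i], tpr[i]))
    cutoff = float(thr[best])
    pred = scores >= cutoff
    acc = float((pred == labels.astype(bool)).mean())
    return ROCResult(
        auc=auc,
        cutoff=cutoff,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        youden=float(j[best]),
        accuracy=acc,
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        flipped=flipped,
    )


@dataclass
class SVMResult:
    feature_indices: tuple[int, ...]
    accuracy_pct: float
    best_C: float
    best_gamma: float
    confusion: dict[str, int] = field(default_factory=dict)  # tn/fp/fn/tp

    @property
    def subset_key(self) -> str:
        return "".join(str(i + 1) for i in self.feature_indices)


def _loo_accuracy(X: np.ndarray, y: np.ndarray, C: float, gamma: float) -> tuple[float, np.ndarray]:
    """Leave-one-out accuracy with per-fold standardization (no leakage)."""
    n = len(y)
    pred = np.empty(n, dtype=int)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(C=C, gamma=gamma, kernel="rbf")
        clf.fit((X[train] - mu) / sd, y[train])
        pred[i] = clf.predict(((X[i] - mu) / sd)[None, :])[0]
    return float((pred == y).mean()), pred


class LooGridSVC(BaseEstimator, ClassifierMixin):
    """RBF soft-margin SVM with leave-one-out grid search.

    For every (C, gamma) on the grid the leave-one-out accuracy of an RBF
    SVM is computed, with feature standardization refit inside every fold.
    The reported model is the grid maximum; ties resolve to the smallest C,
    then the smallest gamma. By default the selected (C, gamma) is the pair
    whose LOO estimate is reported (the convention of small-sample
    neuroimaging studies, optimistically biased); ``nested=True`` instead
    re-runs the grid search inside each outer fold on the training subjects
    only, giving an unbiased outer estimate.

    Attributes (after ``fit``): ``loo_accuracy_`` (fraction), ``best_C_``,
    ``best_gamma_``, ``confusion_``, ``predictions_``.
    """

    def __init__(self, C_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID, nested: bool = False):
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.nested = nested

    @staticmethod
    def _clean_features(X: np.ndarray) -> np.ndarray:
        scale = np.maximum(np.abs(X).max(axis=0), 1.0)
        keep = X.std(axis=0) > 1e-12 * scale
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} constant feature(s)", stacklevel=3)
        return X[:, keep]

    def _grid_best(self, X: np.ndarray, y: np.ndarray) -> tuple[float, float, float, np.ndarray]:
        best = (-1.0, None, None, None)
        for C in self.C_grid:
            for gamma in self.gamma_grid:
                acc, pred = _loo_accuracy(X, y, C, gamma)
                if acc > best[0]:
                    best = (acc, C, gamma, pred)
        return best

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LooGridSVC":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y).astype(int)
        n = len(y)
        if n < 4:
            raise ValueError("need at least 4 subjects")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        X = self._clean_features(X)
        if X.shape[1] == 0:
            # no informative feature: majority-class prediction
            majority = int(np.bincount(y).argmax())
            pred = np.full(n, majority)
            self.best_C_, self.best_gamma_ = float("nan"), float("nan")
            self.loo_accuracy_ = float((pred == y).mean())
            self.predictions_ = pred
        elif self.nested:
            pred = np.empty(n, dtype=int)
            for i in range(n):
                train = np.ones(n, dtype=bool)
                train[i] = False
                _, C, gamma, _ = self._grid_best(X[train], y[train])
                mu, sd = X[train].mean(axis=0), X[train].std(axis=0)
                sd[sd == 0] = 1.0
                clf = SVC(C=C, gamma=gamma, kernel="rbf")
                clf.fit((X[train] - mu) / sd, y[train])
                pred[i] = clf.predict(((X[i] - mu) / sd)[None, :])[0]
            self.loo_accuracy_ = float((pred == y).mean())
            acc, C, gamma, _ = self._grid_best(X, y)
            self.best_C_, self.best_gamma_ = float(C), float(gamma)
            self.predictions_ = pred
        else:
            acc, C, gamma, pred = self._grid_best(X, y)
            self.loo_accuracy_ = acc
            self.best_C_, self.best_gamma_ = float(C), float(gamma)
            self.predictions_ = pred
        tp = int(((self.predictions_ == 1) & (y == 1)).sum())
        tn = int(((self.predictions_ == 0) & (y == 0)).sum())
        fp = int(((self.predictions_ == 1) & (y == 0)).sum())
        fn = int(((self.predictions_ == 0) & (y == 1)).sum())
        self.confusion_ = dict(tn=tn, fp=fp, fn=fn, tp=tp)
        self._X_fit, self._y_fit = X, y
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mu, sd = self._X_fit.mean(axis=0), self._X_fit.std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(C=self.best_C_, gamma=self.best_gamma_, kernel="rbf")
        clf.fit((self._X_fit - mu) / sd, self._y_fit)
        return clf.predict((X - mu) / sd)


def svm_loo_accuracy(features: np.ndarray, labels: np.ndarray,
                     C_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                     nested: bool = False,
                     feature_indices: tuple[int, ...] | None = None) -> SVMResult:
    """Leave-one-out SVM accuracy (percent) with grid-searched (C, gamma)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    est = LooGridSVC(C_grid=C_grid, gamma_grid=gamma_grid, nested=nested).fit(features, labels)
    return SVMResult(
        feature_indices=feature_indices or tuple(range(features.shape[1])),
        accuracy_pct=est.loo_accuracy_ * 100.0,
        best_C=est.best_C_,
        best_gamma=est.best_gamma_,
        confusion=est.confusion_,
    )


def subset_search(features: np.ndarray, labels: np.ndarray,
                  C_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                  nested: bool = False) -> pd.DataFrame:
    """LOO-SVM accuracy for every nonempty feature subset.

    Features are numbered 1..k and each of the 2^k - 1 subsets is evaluated
    independently; rows are keyed by concatenated indices ("1", "12",
    "134", ...) ordered by subset size then lexicographically, with the best
    subset flagged.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    k = features.shape[1]
    if k > 10:
        raise ValueError("subset search is limited to 10 features (2^k - 1 subsets)")
    rows = []
    for size in range(1, k + 1):
        for combo in combinations(range(k), size):
            res = svm_loo_accuracy(
                features[:, combo], labels, C_grid=C_grid, gamma_grid=gamma_grid,
                nested=nested, feature_indices=combo,
            )
            rows.append(
                dict(subset=res.subset_key, n_features=size,
                     accuracy_pct=res.accuracy_pct, C=res.best_C, gamma=res.best_gamma)
            )
    df = pd.DataFrame(rows)
    df["best"] = df["accuracy_pct"] == df["accuracy_pct"].max()
    return df
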
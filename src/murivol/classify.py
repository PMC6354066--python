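"""Classification-power evaluation.

Linear-SVM discrimination of treated vs untreated animals from structure
volumes, exactly as in small-cohort morphometry practice: per-fold feature
standardization and PCA to 95% explained variance (both fitted on training
folds only, so no information leaks into the test fold), a linear SVM with
C = 1 and no tuning, stratified 3-fold cross-validation scored by ROC AUC
from decision values, and learning curves from repeated stratified
subsampling.

Feature modes: ``single`` (w-scores at the final timepoint), ``longitudinal``
(per-structure volume change rates), ``combined`` (both, 2x features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import accuracy_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "FeatureMatrix",
    "CVReport",
    "LearningCurve",
    "assemble_features",
    "standardize",
    "pca_reduce",
    "cv_linear_svm",
    "learning_curve",
]

FEATURE_MODES = ("single", "longitudinal", "combined")


@dataclass(frozen=True)
class FeatureMatrix:
    X: np.ndarray                 # subjects x features
    y: np.ndarray                 # group labels (0/1)
    feature_names: list[str]
    subjects: list[str]
    mode: str = "single"

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per label")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains missing/non-finite values")
        if X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the number of columns")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.X.shape[0]


def assemble_features(wscores: pd.DataFrame | None,
                      change_rates: pd.DataFrame | None,
                      mode: str = "combined") -> FeatureMatrix:
    """Build the subject-by-structure feature matrix for one analysis mode.

    ``wscores`` / ``change_rates`` are wide tables indexed by subject with one
    column per structure, plus a ``group`` column (identical across tables).
    Missing entries (a subject lacking a timepoint) raise with the offenders
    listed.
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"mode must be one of {FEATURE_MODES}")
    tables = []
    if mode in ("single", "combined"):
        if wscores is None:
            raise ValueError("mode requires the final-timepoint w-score table")
        tables.append(("wscore", wscores))
    if mode in ("longitudinal", "combined"):
        if change_rates is None:
            raise ValueError("mode requires the change-rate table")
        tables.append(("rate", change_rates))
    blocks, names = [], []
    subjects = None
    groups = None
    for prefix, tab in tables:
        bad = tab.index[tab.drop(columns="group").isna().any(axis=1)].tolist()
        if bad:
            raise ValueError(f"subjects with missing features: {bad}")
        if subjects is None:
            subjects = list(tab.index)
            groups = tab["group"]
        elif list(tab.index) != subjects:
            raise ValueError("tables must cover the same subjects in the same order")
        feat = tab.drop(columns="group")
        blocks.append(feat.to_numpy(dtype=float))
        names.extend(f"{prefix}:{c}" for c in feat.columns)
    X = np.hstack(blocks)
    y = pd.Categorical(groups).codes
    return FeatureMatrix(X, y, names, [str(s) for s in subjects], mode)


def standardize(train: np.ndarray, apply_to: np.ndarray | None = None,
                ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Column-wise (x - mean) / SD using TRAIN statistics only.

    Zero-variance training columns are dropped from both matrices (indices of
    kept columns returned)."""
    train = np.asarray(train, dtype=float)
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    keep = np.flatnonzero(sd > 0)
    if keep.size < train.shape[1]:
        warnings.warn(f"dropping {train.shape[1] - keep.size} constant feature(s)")
    tr = (train[:, keep] - mu[keep]) / sd[keep]
    if apply_to is None:
        return tr, tr, list(keep)
    ap = (np.asarray(apply_to, dtype=float)[:, keep] - mu[keep]) / sd[keep]
    return tr, ap, list(keep)


def pca_reduce(train: np.ndarray, apply_to: np.ndarray | None = None,
               variance_fraction: float = 0.95):
    """Project onto the fewest principal components reaching the requested
    cumulative explained variance (fitted on the training matrix only)."""
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance fraction must be in (0, 1]")
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("empty training matrix")
    full = PCA()
    full.fit(train)
    cum = np.cumsum(full.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    n_comp = min(n_comp, len(cum))
    tr = full.transform(train)[:, :n_comp]
    if apply_to is None:
        return tr, tr, full, n_comp
    ap = full.transform(np.asarray(apply_to, dtype=float))[:, :n_comp]
    return tr, ap, full, n_comp


@dataclass(frozen=True)
class CVReport:
    fold_aucs: list[float]
    mean_auc: float
    rocs: list[tuple[np.ndarray, np.ndarray]]     # (fpr, tpr) per fold
    fold_assignments: list[np.ndarray]
    fold_accuracies: list[float] = field(default_factory=list)
    seed: int = 0


def _fold_fit_score(X, y, train_idx, test_idx, variance_fraction, C):
    tr, te, _ = standardize(X[train_idx], X[test_idx])
    tr, te, _, _ = pca_reduce(tr, te, variance_fraction)
    clf = SVC(kernel="linear", C=C)
    clf.fit(tr, y[train_idx])
    scores = clf.decision_function(te)
    pred = clf.predict(te)
    return scores, pred, clf


def cv_linear_svm(features: FeatureMatrix, k: int = 3, seed: int = 0,
                  variance_fraction: float = 0.95, C: float = 1.0) -> CVReport:
    """Stratified k-fold CV of the standardize + PCA + linear-SVM pipeline."""
    X, y = features.X, features.y
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("binary classification requires exactly two classes")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest class size {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    aucs, rocs, assigns, accs = [], [], [], []
    for train_idx, test_idx in skf.split(X, y):
        if np.unique(y[test_idx]).size < 2 or np.unique(y[train_idx]).size < 2:
            raise ValueError("a fold lost one of the classes; lower k")
        scores, pred, _ = _fold_fit_score(X, y, train_idx, test_idx,
                                          variance_fraction, C)
        aucs.append(float(roc_auc_score(y[test_idx], scores)))
        fpr, tpr, _ = roc_curve(y[test_idx], scores)
        rocs.append((fpr, tpr))
        accs.append(float(accuracy_score(y[test_idx], pred)))
        assigns.append(test_idx)
    return CVReport(aucs, float(np.mean(aucs)), rocs, assigns, accs, int(seed))


@dataclass(frozen=True)
class LearningCurve:
    sizes: list[int]
    train_mean: np.ndarray
    train_sd: np.ndarray
    test_mean: np.ndarray
    test_sd: np.ndarray
    replicates: int
    seed: int


def learning_curve(features: FeatureMatrix, sizes, replicates: int = 20,
                   k: int = 3, seed: int = 0,
                   variance_fraction: float = 0.95, C: float = 1.0
                   ) -> LearningCurve:
    """Accuracy vs sample size by repeated stratified subsampling.

    For each size, ``replicates`` stratified subsamples (without replacement)
    are drawn; within each, stratified k-fold CV yields test accuracy and the
    training accuracy of the fold models.
    """
    X, y = features.X, features.y
    n = features.n
    sizes = [int(s) for s in sizes]
    if any(s > n for s in sizes):
        raise ValueError("requested sample size exceeds the cohort")
    if any(s < 2 * k for s in sizes):
        raise ValueError(f"each size must be >= 2*k = {2 * k} for stratified CV")
    rng = np.random.default_rng(int(seed))
    tr_m, tr_s, te_m, te_s = [], [], [], []
    for size in sizes:
        tr_accs, te_accs = [], []
        for _ in range(replicates):
            idx = _stratified_subsample(y, size, rng)
            skf = StratifiedKFold(n_splits=k, shuffle=True,
                                  random_state=int(rng.integers(2 ** 31)))
            fold_tr, fold_te = [], []
            for a, b in skf.split(X[idx], y[idx]):
                train_idx, test_idx = idx[a], idx[b]
                scores, pred, clf = _fold_fit_score(X, y, train_idx, test_idx,
                                                    variance_fraction, C)
                tr_std, _, kept = standardize(X[train_idx])
                tr_p, _, _, _ = pca_reduce(tr_std, None, variance_fraction)
                fold_tr.append(accuracy_score(y[train_idx], clf.predict(tr_p)))
                fold_te.append(accuracy_score(y[test_idx], pred))
            tr_accs.append(np.mean(fold_tr))
            te_accs.append(np.mean(fold_te))
        tr_m.append(np.mean(tr_accs))
        tr_s.append(np.std(tr_accs, ddof=1) if len(tr_accs) > 1 else 0.0)
        te_m.append(np.mean(te_accs))
        te_s.append(np.std(te_accs, ddof=1) if len(te_accs) > 1 else 0.0)
    return LearningCurve(sizes, np.array(tr_m), np.array(tr_s),
                         np.array(te_m), np.array(te_s), replicates, int(seed))


def _stratified_subsample(y, size, rng) -> np.ndarray:
    """Subsample preserving class proportions as closely as possible."""
    classes, counts = np.unique(y, return_counts=True)
    n = y.size
    take = np.floor(counts * size / n).astype(int)
    take = np.maximum(take, 1)
    while take.sum() < size:
        frac = counts * size / n - take
        take[np.argmax(frac)] += 1
    while take.sum() > size:
        take[np.argmax(take)] -= 1
    idx = []
    for c, t in zip(classes, take):
        pool = np.flatnonzero(y == c)
        idx.append(rng.choice(pool, size=min(t, pool.size), replace=False))
    return np.concatenate(idx)
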
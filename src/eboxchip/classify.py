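"""Bound-vs-unbound site classification from sequence and shape features.

Aligned fixed-width windows around a shared E-box core are labelled 1
(within ChIP peaks, bound) or 0 (random intronic occurrences, unbound).
Sequence features are one-hot encodings of the flank positions only (the
core is constant across sites and carries no information); shape features
cover every window position, since flanking bases alter shape at the core
edges.  Models are L2-regularized linear regressions on the 0/1 response,
scored by the linear predictor, and evaluated by pooled out-of-fold
ROC/AUC under stratified 10-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.metrics import roc_curve, auc as _trapezoid_auc
from sklearn.model_selection import StratifiedKFold

from .shape import ShapeTable, predict_shape

__all__ = [
    "FEATURE_SETS",
    "SiteSet",
    "ModelSpec",
    "RocResult",
    "build_features",
    "fit_ridge",
    "roc_auc",
    "cross_validate",
    "compare_models",
]

FEATURE_SETS = ("sequence", "shape4", "sequence+shape4", "sequence+mgw")
_BASES = "ACGT"
PAD = 2  # bp of genomic context carried on each side so shape is defined window-wide


@dataclass
class SiteSet:
    """Aligned, labelled site windows sharing one central E-box core.

    ``sequences`` have length window_width + 2*PAD: each window carries PAD
    extra genomic bases per side so every window position has a defined
    pentamer shape.  ``core_offset`` is the core start within the window
    (excluding the pad).
    """

    sequences: list[str]
    labels: np.ndarray
    window_width: int
    core: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sequences) != self.labels.size:
            raise ValueError("one label per sequence required")
        want = self.window_width + 2 * PAD
        for s in self.sequences:
            if len(s) != want:
                raise ValueError(f"sequence length {len(s)} != window+2*pad = {want}")
        if not set(self.labels.tolist()) <= {0, 1}:
            raise ValueError("labels must be 0/1")

    @property
    def core_offset(self) -> int:
        return (self.window_width - len(self.core)) // 2

    def check_alignment(self) -> None:
        a = PAD + self.core_offset
        cores = {s[a: a + len(self.core)].upper() for s in self.sequences}
        if cores != {self.core.upper()}:
            raise ValueError(f"mixed or shifted cores in site set: {sorted(cores)}")


@dataclass
class ModelSpec:
    feature_set: str = "sequence+shape4"
    ridge_lambda: float | None = None  # None -> inner-CV grid search
    lambda_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.ridge_lambda is not None and self.ridge_lambda < 0:
            raise ValueError("ridge penalty must be >= 0")


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    fold_aucs: list[float] = field(default_factory=list)


def _one_hot_flanks(sites: SiteSet) -> np.ndarray:
    w, k = sites.window_width, len(sites.core)
    flank_cols = [j for j in range(w) if not (sites.core_offset <= j < sites.core_offset + k)]
    X = np.zeros((len(sites.sequences), 4 * len(flank_cols)))
    for i, s in enumerate(sites.sequences):
        win = s[PAD: PAD + w].upper()
        for c, j in enumerate(flank_cols):
            X[i, 4 * c + _BASES.index(win[j])] = 1.0
    return X


def _shape_block(sites: SiteSet, table: ShapeTable, mgw_only: bool) -> np.ndarray:
    rows = []
    for s in sites.sequences:
        sh = predict_shape(s, table)[PAD: PAD + sites.window_width]
        rows.append(sh[:, :1].ravel() if mgw_only else sh.ravel())
    return np.asarray(rows)


def build_features(
    sites: SiteSet, table: ShapeTable, feature_set: str = "sequence+shape4"
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and 0/1 labels for one feature set.

    Columns are raw (unstandardized); cross_validate standardizes using
    training folds only.  Sequence block: 4 x (window - core) columns.
    shape4 adds 4 x window columns; mgw adds window columns.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    sites.check_alignment()
    blocks = []
    if feature_set != "shape4":
        blocks.append(_one_hot_flanks(sites))
    if feature_set in ("shape4", "sequence+shape4"):
        blocks.append(_shape_block(sites, table, mgw_only=False))
    elif feature_set == "sequence+mgw":
        blocks.append(_shape_block(sites, table, mgw_only=True))
    return np.hstack(blocks), sites.labels.copy()


def fit_ridge(
    X: np.ndarray, y: np.ndarray, ridge_lambda: float, fit_intercept: bool = True
) -> tuple[np.ndarray, float]:
    """w = argmin ||Xw - y||^2 + lambda ||w||^2 (intercept unpenalized)."""
    if ridge_lambda < 0:
        raise ValueError("ridge penalty must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("X rows must match y length")
    model = Ridge(alpha=ridge_lambda, fit_intercept=fit_intercept, solver="cholesky")
    model.fit(X, y)
    return model.coef_.ravel(), float(model.intercept_) if fit_intercept else 0.0


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC curve and trapezoidal AUC; ties count one half.

    Equals the probability that a random positive outscores a random
    negative.  Raises when only one class is present.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: both classes must be present")
    fpr, tpr, _ = roc_curve(y, s)
    return RocResult(float(_trapezoid_auc(fpr, tpr)), fpr, tpr)


def _standardize(train: np.ndarray, *others: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return [(a - mu) / sd for a in (train, *others)]


def _pick_lambda(X: np.ndarray, y: np.ndarray, spec: ModelSpec) -> float:
    """Inner 5-fold grid search on the training data, pooled-AUC objective."""
    inner = StratifiedKFold(n_splits=5, shuffle=True, random_state=spec.seed + 1)
    best_lam, best_auc = spec.lambda_grid[0], -1.0
    splits = list(inner.split(X, y))
    for lam in spec.lambda_grid:
        scores = np.empty(y.size)
        for tr, te in splits:
            Xtr, Xte = _standardize(X[tr], X[te])
            w, b = fit_ridge(Xtr, y[tr], lam)
            scores[te] = Xte @ w + b
        a = roc_auc(scores, y).auc
        if a > best_auc:
            best_lam, best_auc = lam, a
    return best_lam


def cross_validate(X: np.ndarray, y: np.ndarray, spec: ModelSpec) -> RocResult:
    """Stratified k-fold CV; AUC from pooled out-of-fold linear predictors.

    Standardization and (when ridge_lambda is None) the inner lambda grid
    search use training folds only.  Per-fold AUCs are also reported.
    """
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < spec.n_folds:
        raise ValueError(f"each class needs >= n_folds={spec.n_folds} members")
    skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
    pooled = np.empty(y.size)
    fold_aucs = []
    for tr, te in skf.split(X, y):
        lam = spec.ridge_lambda if spec.ridge_lambda is not None else _pick_lambda(X[tr], y[tr], spec)
        Xtr, Xte = _standardize(X[tr], X[te])
        w, b = fit_ridge(Xtr, y[tr], lam)
        pooled[te] = Xte @ w + b
        if len(np.unique(y[te])) == 2:
            fold_aucs.append(roc_auc(pooled[te], y[te]).auc)
    res = roc_auc(pooled, y)
    res.fold_aucs = fold_aucs
    return res


def compare_models(
    sites: SiteSet,
    table: ShapeTable,
    ridge_lambda: float | None = None,
    seed: int = 0,
    n_folds: int = 10,
) -> dict[str, RocResult]:
    """Cross-validated AUC for all four feature sets on identical folds."""
    out = {}
    for fs in FEATURE_SETS:
        spec = ModelSpec(feature_set=fs, ridge_lambda=ridge_lambda, seed=seed, n_folds=n_folds)
        X, y = build_features(sites, table, fs)
        out[fs] = cross_validate(X, y, spec)
    return out
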
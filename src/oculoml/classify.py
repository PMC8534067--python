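"""Cross-validated dyslexia classification with permutation significance.

Analysis 1 of the pipeline: a fixed roster of linear and non-linear
classifiers is evaluated by stratified 5-fold cross-validation.  At each
fold the train and test blocks are standardized with the *training*
mean/SD only, the model is fitted on the training block, and a confusion
table is computed on the held-out block; accuracy, sensitivity and
specificity are averaged over folds.  No hyperparameter tuning is
performed — every hyperparameter is written explicitly into the roster.
The best model is the lexicographic maximum on (accuracy, sensitivity,
specificity), remaining ties broken by roster order.

Statistical significance is assessed by a label permutation test: the
class labels of the whole dataset are permuted, the full CV procedure is
re-run, and the p-value is the exceedance fraction
``#(permuted >= observed) / R`` (plain estimator, so a score above all
R = 1000 replicates reports 0.000; the bias-corrected
``(1 + #) / (1 + R)`` estimator is available behind a flag).

The positive class is "dyslexic": sensitivity measures detection of the
condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.covariance import LedoitWolf
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "POSITIVE_CLASS",
    "ModelSpec",
    "ConfusionCounts",
    "Metrics",
    "FoldRecord",
    "CVEvaluation",
    "PermutationResult",
    "build_roster",
    "make_folds",
    "standardize_fold",
    "run_cv",
    "compute_metrics",
    "select_best",
    "permutation_test",
]

POSITIVE_CLASS = "dyslexic"
EPS_SD = 1e-12  # constant-column guard for the standardization divisor


@dataclass(frozen=True)
class ModelSpec:
    """One roster entry: family id, an estimator factory and the full
    explicit hyperparameter record (so results do not drift with library
    defaults)."""

    name: str
    factory: Callable[[int], object]
    params: dict
    linear: bool


def build_roster(seed: int = 0) -> list[ModelSpec]:
    """The fixed model roster, linear families first.

    Logistic regression carries an L1 (lasso) penalty; the RBF kernels use
    gamma = 0.01; the small iteration budgets suit cohorts of n < a few
    hundred subjects.
    """
    entries = [
        ("logistic_regression", True,
         dict(l1_ratio=1.0, C=1.0, solver="liblinear", max_iter=1000),
         lambda s, p: LogisticRegression(random_state=s, **p)),
        ("linear_svm", True,
         dict(kernel="linear", C=1.0),
         lambda s, p: SVC(random_state=s, **p)),
        # descriptor tables are wide (features >> subjects per class), so
        # both discriminant models use shrinkage-regularized covariances
        ("lda", True, dict(solver="lsqr", shrinkage="auto"),
         lambda s, p: LinearDiscriminantAnalysis(**p)),
        ("gaussian_nb", True, dict(var_smoothing=1e-9),
         lambda s, p: GaussianNB(**p)),
        ("rbf_svm", False,
         dict(kernel="rbf", gamma=0.01, C=1.0),
         lambda s, p: SVC(random_state=s, **p)),
        ("qda", False, dict(solver="eigen", covariance="ledoit_wolf"),
         lambda s, p: QuadraticDiscriminantAnalysis(
             solver="eigen", covariance_estimator=LedoitWolf())),
        ("knn", False, dict(n_neighbors=5, weights="uniform"),
         lambda s, p: KNeighborsClassifier(**p)),
        ("gaussian_process", False,
         dict(max_iter_predict=20, n_restarts_optimizer=0),
         lambda s, p: GaussianProcessClassifier(random_state=s, **p)),
        ("mlp", False,
         dict(hidden_layer_sizes=(10,), solver="lbfgs", max_iter=1000, alpha=1e-4),
         lambda s, p: MLPClassifier(random_state=s, **p)),
        ("random_forest", False,
         dict(n_estimators=100, max_features="sqrt"),
         lambda s, p: RandomForestClassifier(random_state=s, **p)),
        ("decision_tree", False, dict(criterion="gini"),
         lambda s, p: DecisionTreeClassifier(random_state=s, **p)),
    ]
    return [
        ModelSpec(name=name, linear=linear, params=dict(params),
                  factory=(lambda s, _p=params, _f=fac: _f(s, dict(_p))))
        for name, linear, params, fac in entries
    ]


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be >= 0")
        if self.tp + self.fn + self.tn + self.fp == 0:
            raise ValueError("empty confusion table")


@dataclass(frozen=True)
class Metrics:
    """Accuracy / sensitivity / specificity in percent; an undefined
    metric (empty positive or negative class) is NaN and listed in
    ``undefined`` rather than silently reported as 0."""

    accuracy: float
    sensitivity: float
    specificity: float
    undefined: tuple[str, ...] = ()


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), in percent."""
    total = counts.tp + counts.fn + counts.tn + counts.fp
    acc = 100.0 * (counts.tp + counts.tn) / total
    undefined = []
    if counts.tp + counts.fn > 0:
        sens = 100.0 * counts.tp / (counts.tp + counts.fn)
    else:
        sens, undefined = np.nan, undefined + ["sensitivity"]
    if counts.tn + counts.fp > 0:
        spec = 100.0 * counts.tn / (counts.tn + counts.fp)
    else:
        spec, undefined = np.nan, undefined + ["specificity"]
    return Metrics(accuracy=acc, sensitivity=sens, specificity=spec,
                   undefined=tuple(undefined))


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

@dataclass
class FoldRecord:
    """Per-fold artifacts kept for leakage audits: the standardization
    parameters fitted on the training block and a fingerprint of the
    fitted model's learned arrays."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    model_fingerprint: Optional[np.ndarray]
    counts: ConfusionCounts
    metrics: Metrics


@dataclass
class CVEvaluation:
    model: str
    folds: list[FoldRecord]
    mean_accuracy: float
    mean_sensitivity: float
    mean_specificity: float
    seed: int


def make_folds(y: np.ndarray, k: int = 5, seed: int = 0
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified, shuffled fold assignments (fixed before any fitting)."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(len(y)), y)]


def standardize_fold(x_train: np.ndarray, x_test: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Standardize both blocks with the training mean/SD only.

    A constant column gets divisor ``max(SD, 1e-12)`` so it stays defined.
    """
    mean = x_train.mean(axis=0)
    scale = np.maximum(x_train.std(axis=0), EPS_SD)
    return (x_train - mean) / scale, (x_test - mean) / scale, mean, scale


def _fingerprint(model) -> Optional[np.ndarray]:
    parts = []
    for attr in ("coef_", "intercept_", "dual_coef_", "theta_", "xbar_",
                 "feature_importances_", "means_"):
        v = getattr(model, attr, None)
        if v is not None:
            parts.append(np.ravel(np.asarray(v, dtype=float)))
    return np.concatenate(parts) if parts else None


def _as_binary(labels: Sequence, positive: str = POSITIVE_CLASS) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "iub":
        return y.astype(int)
    return (y == positive).astype(int)


def run_cv(x, labels, roster: Sequence[ModelSpec], k: int = 5, seed: int = 0,
           folds: Optional[list[tuple[np.ndarray, np.ndarray]]] = None
           ) -> dict[str, CVEvaluation]:
    """Evaluate every roster model over the same k folds.

    ``folds`` may be supplied to pin the assignments (leakage audits,
    fixed-fold permutation variants); otherwise stratified shuffled folds
    are derived from ``seed``.  A fold whose training block contains a
    single class raises, signalling a degenerate split.
    """
    x = np.asarray(x, dtype=float)
    y = _as_binary(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain exactly two classes")
    if folds is None:
        if min(np.bincount(y)) < k:
            raise ValueError(f"need at least {k} subjects per class")
        folds = make_folds(y, k=k, seed=seed)

    evaluations: dict[str, CVEvaluation] = {}
    for spec in roster:
        records: list[FoldRecord] = []
        for tr, te in folds:
            if len(np.unique(y[tr])) < 2:
                raise ValueError("degenerate fold: single class in train")
            xtr, xte, mean, scale = standardize_fold(x[tr], x[te])
            model = spec.factory(seed)
            model.fit(xtr, y[tr])
            pred = np.asarray(model.predict(xte))
            counts = ConfusionCounts(
                tp=int(np.sum((pred == 1) & (y[te] == 1))),
                fn=int(np.sum((pred == 0) & (y[te] == 1))),
                tn=int(np.sum((pred == 0) & (y[te] == 0))),
                fp=int(np.sum((pred == 1) & (y[te] == 0))))
            records.append(FoldRecord(
                train_idx=tr, test_idx=te, scaler_mean=mean,
                scaler_scale=scale, model_fingerprint=_fingerprint(model),
                counts=counts, metrics=compute_metrics(counts)))
        evaluations[spec.name] = CVEvaluation(
            model=spec.name, folds=records,
            mean_accuracy=float(np.mean([r.metrics.accuracy for r in records])),
            mean_sensitivity=float(np.nanmean(
                [r.metrics.sensitivity for r in records])),
            mean_specificity=float(np.nanmean(
                [r.metrics.specificity for r in records])),
            seed=seed)
    return evaluations


def select_best(evaluations: dict[str, CVEvaluation],
                roster_order: Optional[Sequence[str]] = None) -> str:
    """Lexicographic maximum on (accuracy, sensitivity, specificity);
    full ties resolve to the earliest roster entry."""
    if not evaluations:
        raise ValueError("no evaluations to select from")
    order = list(roster_order) if roster_order else list(evaluations)

    def key(name: str):
        e = evaluations[name]
        nn = lambda v: -np.inf if np.isnan(v) else v
        return (nn(e.mean_accuracy), nn(e.mean_sensitivity),
                nn(e.mean_specificity), -order.index(name))

    return max((n for n in order if n in evaluations), key=key)


# --------------------------------------------------------------------------
# permutation significance
# --------------------------------------------------------------------------

@dataclass
class PermutationResult:
    model: str
    observed_accuracy: float
    permuted_accuracies: np.ndarray
    p_value: float
    seed: int


def permutation_test(x, labels, spec: ModelSpec, n_permutations: int = 1000,
                     seed: int = 0, k: int = 5,
                     observed: Optional[float] = None,
                     refit_folds: bool = True,
                     bias_corrected: bool = False) -> PermutationResult:
    """Label-permutation null distribution of the model's mean CV accuracy.

    Each replicate permutes the labels of the entire dataset and repeats
    the full CV procedure (fold construction included; set
    ``refit_folds=False`` to keep the original fold assignments).  The
    p-value is the probability of a permuted score at least equal to the
    observed one.  ``observed`` may be supplied when already computed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = np.asarray(x, dtype=float)
    y = _as_binary(labels)
    ss = np.random.SeedSequence(seed)
    fold_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    if observed is None:
        observed = run_cv(x, y, [spec], k=k, seed=fold_seed)[spec.name] \
            .mean_accuracy
    base_folds = None if refit_folds else make_folds(y, k=k, seed=fold_seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.generate_state(n_permutations + 1)[1:] % (2 ** 31)
    scores = np.empty(n_permutations)
    for r in range(n_permutations):
        y_perm = y[rng.permutation(len(y))]
        folds = base_folds
        ev = run_cv(x, y_perm, [spec], k=k, seed=int(child_seeds[r]),
                    folds=folds)[spec.name]
        scores[r] = ev.mean_accuracy
    exceed = int(np.sum(scores >= observed))
    if bias_corrected:
        p = (1 + exceed) / (1 + n_permutations)
    else:
        p = exceed / n_permutations
    return PermutationResult(model=spec.name, observed_accuracy=observed,
                             permuted_accuracies=scores, p_value=float(p),
                             seed=seed)
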
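"""Reading-speed regression with fold-internal feature selection.

Analysis 2 of the pipeline: predict meaningful-text reading speed
(words/min) from eye-movement descriptor features.  At each of the 5 CV
folds the 10 features with the largest |Pearson correlation| with speed
*on the training rows only* are selected, the selected columns are
standardized with the training statistics, the model is fitted and the
held-out block predicted.  Out-of-fold predictions are pooled across
folds before computing the two evaluation metrics:

* MAPE = 100 * mean(|y - yhat| / y) (speeds must be positive);
* the Bravais-Pearson correlation r between pooled predictions and the
  measured speeds.

The best model is the one with the lowest MAPE.  Feature-selection
stability is summarized by the features chosen in at least 4 of 5 folds,
each with its full-dataset correlation and two-sided p-value (t-transform
of r).  The absolute-value selection rule keeps strongly *negatively*
correlated descriptors; signed-descending selection is available behind a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .classify import standardize_fold

__all__ = [
    "RegressionModelSpec",
    "FeatureSelectionRecord",
    "RegressionEvaluation",
    "build_regression_roster",
    "select_features",
    "mape",
    "run_cv_regression",
    "stability_report",
]


@dataclass(frozen=True)
class RegressionModelSpec:
    name: str
    factory: Callable[[int], object]
    params: dict


def build_regression_roster(seed: int = 0) -> list[RegressionModelSpec]:
    """Linear regression, a two-layer neural network of ~60 trainable
    parameters (hidden size 5 on 10 inputs: 10*5 + 5 + 5 + 1 = 61), and
    RBF support-vector regression with gamma = 0.01."""
    entries = [
        ("linear_regression", dict(), lambda s, p: LinearRegression(**p)),
        ("mlp_60", dict(hidden_layer_sizes=(5,), solver="lbfgs", max_iter=2000, alpha=1e-4),
         lambda s, p: MLPRegressor(random_state=s, **p)),
        ("rbf_svr", dict(kernel="rbf", gamma=0.01, C=1.0, epsilon=0.1),
         lambda s, p: SVR(**p)),
    ]
    return [RegressionModelSpec(name=n, params=dict(p),
                                factory=(lambda s, _p=p, _f=f: _f(s, dict(_p))))
            for n, p, f in entries]


# --------------------------------------------------------------------------
# feature selection
# --------------------------------------------------------------------------

def _pearson_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column with y; constant columns give NaN."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[sx == 0] = np.nan
    if sy == 0:
        r[:] = np.nan
    return r


def select_features(x, y, feature_names: Sequence[str], m: int = 10,
                    absolute: bool = True) -> tuple[list[str], dict[str, float]]:
    """The m features most correlated with speed on the given rows.

    Ranks by |r| (or signed r with ``absolute=False``); ties break by
    feature name; constant columns are excluded.  Returns the selected
    names (all of them when fewer than m are usable) and their train-set
    correlations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 rows to correlate")
    r = _pearson_columns(x, y)
    usable = [(name, r[j]) for j, name in enumerate(feature_names)
              if np.isfinite(r[j])]
    score = (lambda v: abs(v)) if absolute else (lambda v: v)
    usable.sort(key=lambda nv: (-score(nv[1]), nv[0]))
    chosen = usable[:m]
    return [n for n, _ in chosen], {n: float(v) for n, v in chosen}


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def mape(y_true, y_pred) -> float:
    """Mean absolute percentage error, in percent."""
    y = np.asarray(y_true, dtype=float)
    yh = np.asarray(y_pred, dtype=float)
    if np.any(y <= 0):
        raise ValueError("MAPE requires strictly positive true values")
    return float(100.0 * np.mean(np.abs(y - yh) / y))


# --------------------------------------------------------------------------
# cross-validated evaluation
# --------------------------------------------------------------------------

@dataclass
class FeatureSelectionRecord:
    """Per-fold selected feature names with train-set correlations."""

    per_fold: list[dict[str, float]]

    def counts(self) -> dict[str, int]:
        c: dict[str, int] = {}
        for sel in self.per_fold:
            for name in sel:
                c[name] = c.get(name, 0) + 1
        return c


@dataclass
class RegressionEvaluation:
    model: str
    predictions: pd.Series  # pooled out-of-fold, index = subject order
    mape: float
    pearson_r: float
    fold_mape: list[float]
    seed: int


def run_cv_regression(x, speeds, roster: Sequence[RegressionModelSpec],
                      feature_names: Optional[Sequence[str]] = None,
                      k: int = 5, m: int = 10, seed: int = 0,
                      folds: Optional[list] = None, absolute: bool = True
                      ) -> tuple[dict[str, RegressionEvaluation],
                                 FeatureSelectionRecord]:
    """Fold-safe selection + standardization + fit for every roster model.

    Selection and standardization always use the training rows only; the
    selected set is therefore shared by all models of a fold.  Pooled
    out-of-fold predictions give MAPE and Pearson r per model.
    """
    if isinstance(x, pd.DataFrame):
        feature_names = list(x.columns)
        x = x.to_numpy(dtype=float)
    else:
        x = np.asarray(x, dtype=float)
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(x.shape[1])]
    y = np.asarray(speeds, dtype=float)
    if np.any(y <= 0):
        raise ValueError("speeds must be strictly positive")
    if folds is None:
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [(tr.copy(), te.copy()) for tr, te in kf.split(x)]

    name_to_col = {n: j for j, n in enumerate(feature_names)}
    selection: list[dict[str, float]] = []
    preds = {spec.name: np.full(len(y), np.nan) for spec in roster}
    fold_mapes: dict[str, list[float]] = {spec.name: [] for spec in roster}
    for tr, te in folds:
        names, corr = select_features(x[tr], y[tr], feature_names, m=m,
                                      absolute=absolute)
        selection.append(corr)
        cols = [name_to_col[n] for n in names]
        xtr, xte, _, _ = standardize_fold(x[np.ix_(tr, cols)],
                                          x[np.ix_(te, cols)])
        for spec in roster:
            model = spec.factory(seed)
            model.fit(xtr, y[tr])
            p = np.asarray(model.predict(xte), dtype=float)
            preds[spec.name][te] = p
            fold_mapes[spec.name].append(mape(y[te], p))

    record = FeatureSelectionRecord(per_fold=selection)
    out: dict[str, RegressionEvaluation] = {}
    for spec in roster:
        p = preds[spec.name]
        r = float(stats.pearsonr(p, y).statistic) if len(y) > 2 else np.nan
        out[spec.name] = RegressionEvaluation(
            model=spec.name, predictions=pd.Series(p), mape=mape(y, p),
            pearson_r=r, fold_mape=fold_mapes[spec.name], seed=seed)
    return out, record


def select_best_regression(evaluations: dict[str, RegressionEvaluation]) -> str:
    """Lowest MAPE wins; ties break by model name for determinism."""
    return min(evaluations, key=lambda n: (evaluations[n].mape, n))


def stability_report(record: FeatureSelectionRecord, x, speeds,
                     feature_names: Optional[Sequence[str]] = None,
                     min_folds: int = 4) -> pd.DataFrame:
    """Features selected in >= ``min_folds`` folds, with the correlation
    and two-sided p-value computed on the entire dataset."""
    if isinstance(x, pd.DataFrame):
        feature_names = list(x.columns)
        x = x.to_numpy(dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    y = np.asarray(speeds, dtype=float)
    name_to_col = {n: j for j, n in enumerate(feature_names)}
    rows = []
    for name, count in sorted(record.counts().items()):
        if count < min_folds:
            continue
        res = stats.pearsonr(x[:, name_to_col[name]], y)
        rows.append(dict(feature=name, n_folds=count,
                         correlation=float(res.statistic),
                         p_value=float(res.pvalue)))
    df = pd.DataFrame(rows, columns=["feature", "n_folds", "correlation",
                                     "p_value"])
    if len(df):
        df = df.sort_values(["n_folds", "feature"],
                            ascending=[False, True]).reset_index(drop=True)
    return df
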
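"""Per-subject feature tables and the two preprocessing rules.

Per-trial descriptors are aggregated per subject into mean, standard
deviation (sample, n-1), coefficient of variation (SD/mean x 100) and
valid-trial count, keyed as ``<test>.<descriptor>.<statistic>`` (the
descriptor name folds in the trial kind, e.g.
``vergence.convergence_latency_ms.mean``).  Cells that cannot be computed
— no valid trial, undefined CoV at zero mean, an undefined regressive
percentage — are *aberrant*: they stay in the table but are flagged in a
boolean mask.

Two cleaning rules mirror the downstream analyses' treatment of aberrant
values and outliers:

* classification — aberrant cells are set to 0 (outliers are taken to be
  informative of recording quality rather than random);
* regression — within each diagnostic class and each column, values
  strictly below the 3rd or strictly above the 97th percentile are
  replaced by the within-class column mean (computed before replacement);
  aberrant cells are likewise replaced by that mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import events as ev
from .simulate import SACCADE_KINDS, VERGENCE_KINDS

__all__ = [
    "FeatureMatrix",
    "aggregate_values",
    "trial_table_values",
    "reading_values",
    "aggregate_subject",
    "build_feature_matrix",
    "clean_for_classification",
    "clean_for_regression",
    "shuffle_rows",
]

STATISTICS = ("mean", "std", "cov", "n")

_KIND_SHORT = {
    "convergence": "convergence",
    "divergence": "divergence",
    "saccade-left": "left",
    "saccade-right": "right",
}


@dataclass
class FeatureMatrix:
    """Subjects x features table with labels, reading speeds and an
    aberrant-cell mask (True = aberrant)."""

    values: pd.DataFrame
    mask: pd.DataFrame
    labels: pd.Series
    speed: pd.Series

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("mask must have the same shape as values")
        for vec in (self.labels, self.speed):
            if len(vec) != len(self.values):
                raise ValueError("labels/speed must match the row count")

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.mask.copy(),
                             self.labels.copy(), self.speed.copy())

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------

def aggregate_values(values) -> dict:
    """Mean / sample SD / CoV / count of one descriptor's valid trials.

    Returns ``{stat: (value, aberrant)}``.  No valid trials makes every
    statistic aberrant; a single trial leaves the SD (and CoV) undefined;
    a zero mean leaves the CoV undefined.
    """
    x = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    n = len(x)
    out = {"n": (float(n), False)}
    if n == 0:
        out.update(mean=(0.0, True), std=(0.0, True), cov=(0.0, True))
        return out
    mean = float(np.mean(x))
    out["mean"] = (mean, False)
    if n < 2:
        out.update(std=(0.0, True), cov=(0.0, True))
        return out
    sd = float(np.std(x, ddof=1))
    out["std"] = (sd, False)
    if mean == 0.0:
        out["cov"] = (0.0, True)
    else:
        out["cov"] = (sd / mean * 100.0, False)
    return out


def trial_table_values(table: pd.DataFrame) -> dict[str, list[float]]:
    """Split a per-trial descriptor table into per-(kind, descriptor)
    value lists, valid trials only."""
    out: dict[str, list[float]] = {}
    for kind, sub in table.groupby("kind", sort=True):
        short = _KIND_SHORT.get(kind, kind)
        valid = sub[sub["valid"]]
        for col in ev.DESCRIPTOR_COLUMNS:
            if kind in VERGENCE_KINDS and col == "disconjugacy_deg":
                continue  # undefined for vergence trials
            out[f"{short}_{col}"] = list(valid[col].to_numpy())
    return out


def reading_values(rd: "ev.ReadingDescriptors") -> dict[str, list[float]]:
    """Descriptor value lists of one reading recording."""
    out: dict[str, list[float]] = {}
    if not rd.valid:
        keys = ["fixation_duration_ms", "disconj_drift_deg",
                "progressive_amplitude_deg", "regressive_amplitude_deg",
                "peak_velocity_deg_s", "avg_velocity_deg_s",
                "left_amplitude_deg", "right_amplitude_deg",
                "pct_regressive", "n_progressive", "n_regressive"]
        return {k: [] for k in keys}
    sacc = rd.saccades
    prog = sacc[sacc["progressive"]]
    reg = sacc[~sacc["progressive"]]
    out["fixation_duration_ms"] = list(rd.fixation_durations_ms)
    out["disconj_drift_deg"] = list(rd.fixation_drifts_deg)
    out["progressive_amplitude_deg"] = list(prog["amplitude_deg"])
    out["regressive_amplitude_deg"] = list(reg["amplitude_deg"])
    out["peak_velocity_deg_s"] = list(sacc["peak_velocity_deg_s"])
    out["avg_velocity_deg_s"] = list(sacc["avg_velocity_deg_s"])
    out["left_amplitude_deg"] = list(sacc["left_amplitude_deg"])
    out["right_amplitude_deg"] = list(sacc["right_amplitude_deg"])
    # scalar descriptors enter as single-value lists (mean = value)
    out["pct_regressive"] = [] if math.isnan(rd.pct_regressive) \
        else [rd.pct_regressive]
    out["n_progressive"] = [float(rd.n_progressive)]
    out["n_regressive"] = [float(rd.n_regressive)]
    return out


def aggregate_subject(test_values: dict[str, dict[str, list[float]]]) -> dict:
    """Aggregate ``{test: {descriptor: values}}`` into one feature row.

    Returns ``{column_name: (value, aberrant)}`` with columns named
    ``<test>.<descriptor>.<statistic>``.
    """
    row: dict[str, tuple[float, bool]] = {}
    for test, descs in test_values.items():
        for desc, values in descs.items():
            stats = aggregate_values(values)
            for stat in STATISTICS:
                row[f"{test}.{desc}.{stat}"] = stats[stat]
    return row


def build_feature_matrix(rows: list[dict], subject_ids: list[str],
                         labels: list[str], speeds: list[float]
                         ) -> FeatureMatrix:
    """Assemble aggregated subject rows into a rectangular FeatureMatrix.

    Columns are the sorted union of all row keys; a column missing for a
    subject becomes an aberrant 0 cell.
    """
    cols = sorted({k for row in rows for k in row})
    values = np.zeros((len(rows), len(cols)))
    mask = np.zeros((len(rows), len(cols)), dtype=bool)
    for i, row in enumerate(rows):
        for j, c in enumerate(cols):
            if c in row:
                values[i, j], mask[i, j] = row[c]
            else:
                mask[i, j] = True
    vdf = pd.DataFrame(values, index=subject_ids, columns=cols)
    mdf = pd.DataFrame(mask, index=subject_ids, columns=cols)
    return FeatureMatrix(values=vdf, mask=mdf,
                         labels=pd.Series(list(labels), index=subject_ids),
                         speed=pd.Series(list(speeds), index=subject_ids,
                                         dtype=float))


# --------------------------------------------------------------------------
# cleaning rules
# --------------------------------------------------------------------------

def clean_for_classification(fm: FeatureMatrix) -> tuple[FeatureMatrix, float]:
    """Zero every aberrant cell; returns the cleaned matrix and the
    aberrant fraction."""
    out = fm.copy()
    n_aberrant = int(out.mask.to_numpy().sum())
    out.values = out.values.where(~out.mask, 0.0)
    fraction = n_aberrant / out.mask.size if out.mask.size else 0.0
    out.mask.loc[:, :] = False
    return out, fraction


def clean_for_regression(fm: FeatureMatrix,
                         lower_pct: float = 3.0, upper_pct: float = 97.0
                         ) -> tuple[FeatureMatrix, float]:
    """Percentile-based outlier replacement, within diagnostic class.

    For each class and column, values strictly below the ``lower_pct``
    percentile or strictly above the ``upper_pct`` percentile (linear
    interpolation between order statistics) are replaced by the class
    column mean computed *before* any replacement; aberrant cells are
    replaced by the same mean.  Classes never share information.  Returns
    the cleaned matrix and the replaced fraction.
    """
    out = fm.copy()
    vals = out.values.to_numpy()
    mask = out.mask.to_numpy()
    n_replaced = 0
    for cls in out.labels.unique():
        rows = np.flatnonzero((out.labels == cls).to_numpy())
        for j in range(vals.shape[1]):
            cell_ok = ~mask[rows, j]
            good = vals[rows, j][cell_ok]
            if len(good) == 0:
                continue
            m = float(np.mean(good))
            lo = float(np.percentile(good, lower_pct))
            hi = float(np.percentile(good, upper_pct))
            for r, ok in zip(rows, cell_ok):
                v = vals[r, j]
                if not ok or v < lo or v > hi:
                    vals[r, j] = m
                    n_replaced += 1
    out.values = pd.DataFrame(vals, index=out.values.index,
                              columns=out.values.columns)
    out.mask.loc[:, :] = False
    fraction = n_replaced / vals.size if vals.size else 0.0
    return out, fraction


def shuffle_rows(fm: FeatureMatrix, seed: int) -> FeatureMatrix:
    """Deterministically permute subject rows (labels and speeds follow)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(fm.values))
    return FeatureMatrix(values=fm.values.iloc[order],
                         mask=fm.mask.iloc[order],
                         labels=fm.labels.iloc[order],
                         speed=fm.speed.iloc[order])
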
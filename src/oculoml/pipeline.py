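"""Stage orchestration: simulate -> extract -> features -> classify /
regress, with run manifests for byte-level reproducibility.

Each stage reads/writes the plain-text formats of :mod:`oculoml.io`.  A
``manifest.json`` records the configuration hash and per-file SHA-256
checksums; re-running a stage verifies its inputs against the manifest
and fails loudly on a mismatch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import classify as clf
from . import events as ev
from . import features as ft
from . import io as oio
from . import regress as rg
from . import simulate as sim

__all__ = [
    "PipelineConfig",
    "ManifestError",
    "run_pipeline",
    "simulate_stage",
    "extract_stage",
    "features_stage",
    "classify_stage",
    "regress_stage",
    "extract_cohort_features",
]

log = logging.getLogger("oculoml")

TESTS = ("vergence", "saccade", "reading")


@dataclass
class PipelineConfig:
    """Everything a full run depends on; (config, seed) determines every
    output byte."""

    seed: int = 0
    n_control: int = 41
    n_dyslexic: int = 46
    trials_per_condition: int = 20
    n_words: int = 150
    null_effects: bool = False
    folds: int = 5
    n_permutations: int = 1000
    n_selected_features: int = 10
    run_classification: bool = True
    run_regression: bool = True
    extraction: ev.ExtractionConfig = field(default_factory=ev.ExtractionConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        extraction = d.pop("extraction", None)
        cfg = cls(**d)
        if extraction:
            cfg.extraction = ev.ExtractionConfig(**extraction)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def cohort_spec(self) -> sim.CohortSpec:
        effects = sim.GroupEffects.null() if self.null_effects \
            else sim.GroupEffects()
        return sim.CohortSpec(
            n_control=self.n_control, n_dyslexic=self.n_dyslexic,
            trials_per_condition=self.trials_per_condition,
            n_words=self.n_words, effects=effects, seed=self.seed)


class ManifestError(RuntimeError):
    """An input file does not match its manifest checksum."""


# --------------------------------------------------------------------------
# manifests
# --------------------------------------------------------------------------

def _manifest_path(outdir: Path) -> Path:
    return Path(outdir) / "manifest.json"


def _load_manifest(outdir: Path) -> dict:
    p = _manifest_path(outdir)
    if p.exists():
        return json.loads(p.read_text())
    return {"files": {}}


def _record_files(outdir: Path, stage: str, paths: list[Path],
                  config: Optional[dict] = None) -> None:
    man = _load_manifest(outdir)
    if config is not None:
        man["config_hash"] = oio.config_hash(config)
    for p in paths:
        man["files"][str(Path(p).relative_to(outdir))] = oio.file_checksum(p)
    man.setdefault("stages", [])
    if stage not in man["stages"]:
        man["stages"].append(stage)
    _manifest_path(outdir).write_text(json.dumps(man, indent=1, sort_keys=True))


def verify_against_manifest(outdir: Path, paths: list[Path]) -> None:
    """Raise :class:`ManifestError` if any path's checksum disagrees with
    the recorded one (unrecorded files pass)."""
    man = _load_manifest(outdir)
    for p in paths:
        rel = str(Path(p).relative_to(outdir))
        recorded = man["files"].get(rel)
        if recorded is not None and oio.file_checksum(p) != recorded:
            raise ManifestError(f"checksum mismatch for {rel}; "
                                "intermediate file was modified")


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def simulate_stage(config: PipelineConfig, outdir) -> Path:
    """Generate the cohort and write traces + cohort manifest TSV."""
    outdir = Path(outdir)
    tracedir = outdir / "traces"
    tracedir.mkdir(parents=True, exist_ok=True)
    cohort = sim.generate_cohort(config.cohort_spec())
    rows = []
    written = []
    for subj in cohort.subjects:
        entry = {"subject_id": subj.subject_id, "group": subj.group,
                 "reading_speed_wpm": subj.reading_speed}
        for test in TESTS:
            path = tracedir / f"{subj.subject_id}_{test}.tsv"
            oio.write_trace(path, subj.traces[test])
            written += [path, path.with_suffix(".tsv.events.tsv")]
            entry[f"{test}_path"] = str(path.relative_to(outdir))
        rows.append(entry)
    cohort_path = outdir / "cohort.tsv"
    pd.DataFrame(rows).to_csv(cohort_path, sep="\t", index=False)
    _record_files(outdir, "simulate", written + [cohort_path],
                  config=config.to_dict())
    log.info("simulate: %d subjects -> %s", len(rows), tracedir)
    return cohort_path


def extract_stage(config: PipelineConfig, outdir) -> Path:
    """Per-subject per-test descriptor tables from the written traces."""
    outdir = Path(outdir)
    cohort_path = outdir / "cohort.tsv"
    if not cohort_path.exists():
        raise FileNotFoundError(
            "extract stage: missing cohort.tsv — run the simulate stage first")
    manifest = pd.read_csv(cohort_path, sep="\t")
    trialdir = outdir / "trials"
    trialdir.mkdir(exist_ok=True)
    written = []
    for _, row in manifest.iterrows():
        paths = [outdir / row[f"{t}_path"] for t in TESTS]
        verify_against_manifest(outdir, paths)
        for test in ("vergence", "saccade"):
            trace = oio.read_trace(outdir / row[f"{test}_path"])
            table = ev.extract_test_trials(trace, config.extraction)
            p = trialdir / f"{row.subject_id}_{test}_trials.tsv"
            table.to_csv(p, sep="\t", index=False)
            written.append(p)
        trace = oio.read_trace(outdir / row["reading_path"])
        rd = ev.compute_reading_descriptors(trace, config.extraction)
        p = trialdir / f"{row.subject_id}_reading_values.json"
        p.write_text(json.dumps(
            {k: list(map(float, v))
             for k, v in ft.reading_values(rd).items()}))
        written.append(p)
    _record_files(outdir, "extract", written)
    log.info("extract: %d subjects -> %s", len(manifest), trialdir)
    return trialdir


def features_stage(config: PipelineConfig, outdir) -> Path:
    """Aggregate descriptor tables into the subject feature matrix."""
    outdir = Path(outdir)
    trialdir = outdir / "trials"
    cohort_path = outdir / "cohort.tsv"
    if not trialdir.exists() or not cohort_path.exists():
        raise FileNotFoundError(
            "features stage: missing trials/ — run the extract stage first")
    manifest = pd.read_csv(cohort_path, sep="\t")
    rows, ids, labels, speeds = [], [], [], []
    for _, row in manifest.iterrows():
        test_values = {}
        for test in ("vergence", "saccade"):
            p = trialdir / f"{row.subject_id}_{test}_trials.tsv"
            verify_against_manifest(outdir, [p])
            test_values[test] = ft.trial_table_values(
                pd.read_csv(p, sep="\t"))
        p = trialdir / f"{row.subject_id}_reading_values.json"
        verify_against_manifest(outdir, [p])
        test_values["reading"] = json.loads(p.read_text())
        rows.append(ft.aggregate_subject(test_values))
        ids.append(row.subject_id)
        labels.append(row.group)
        speeds.append(row.reading_speed_wpm)
    fm = ft.build_feature_matrix(rows, ids, labels, speeds)
    fm = ft.shuffle_rows(fm, seed=config.seed)
    path = outdir / "features.tsv"
    oio.write_feature_matrix(path, fm)
    _record_files(outdir, "features",
                  [path, path.with_suffix(".tsv.mask.tsv")])
    log.info("features: %s (%d x %d)", path, *fm.values.shape)
    return path


def classify_stage(config: PipelineConfig, outdir) -> Path:
    """Roster CV + permutation test; writes report JSON and histogram."""
    outdir = Path(outdir)
    fpath = outdir / "features.tsv"
    if not fpath.exists():
        raise FileNotFoundError(
            "classify stage: missing features.tsv — run the features stage first")
    verify_against_manifest(outdir, [fpath])
    fm = oio.read_feature_matrix(fpath)
    cleaned, aberrant_fraction = ft.clean_for_classification(fm)
    roster = clf.build_roster(config.seed)
    evals = clf.run_cv(cleaned.values, cleaned.labels, roster,
                       k=config.folds, seed=config.seed)
    order = [s.name for s in roster]
    best_all = clf.select_best(evals, order)
    linear = {n: e for n, e in evals.items()
              if next(s for s in roster if s.name == n).linear}
    nonlinear = {n: e for n, e in evals.items() if n not in linear}
    best_linear = clf.select_best(linear, order)
    best_nonlinear = clf.select_best(nonlinear, order)

    perm_results = {}
    for name in {best_linear, best_nonlinear}:
        spec = next(s for s in roster if s.name == name)
        res = clf.permutation_test(
            cleaned.values.to_numpy(), cleaned.labels.to_numpy(), spec,
            n_permutations=config.n_permutations, seed=config.seed,
            k=config.folds, observed=evals[name].mean_accuracy)
        perm_results[name] = res
        _plot_permutation(res, outdir / f"permutation_{name}.png")

    report = {
        "aberrant_fraction": aberrant_fraction,
        "best_model": best_all,
        "best_linear": best_linear,
        "best_nonlinear": best_nonlinear,
        "models": {n: dict(accuracy=e.mean_accuracy,
                           sensitivity=e.mean_sensitivity,
                           specificity=e.mean_specificity)
                   for n, e in evals.items()},
        "permutation": {n: dict(observed=r.observed_accuracy,
                                p_value=r.p_value,
                                n_permutations=len(r.permuted_accuracies))
                        for n, r in perm_results.items()},
    }
    path = outdir / "classification_report.json"
    path.write_text(json.dumps(report, indent=1, sort_keys=True))
    _record_files(outdir, "classify", [path])
    log.info("classify: best=%s acc=%.1f%%", best_all,
             evals[best_all].mean_accuracy)
    return path


def regress_stage(config: PipelineConfig, outdir) -> Path:
    """Reading-speed regression; writes report JSON, stability table and
    the observed-vs-predicted scatter."""
    outdir = Path(outdir)
    fpath = outdir / "features.tsv"
    if not fpath.exists():
        raise FileNotFoundError(
            "regress stage: missing features.tsv — run the features stage first")
    verify_against_manifest(outdir, [fpath])
    fm = oio.read_feature_matrix(fpath)
    cleaned, _ = ft.clean_for_regression(fm)
    roster = rg.build_regression_roster(config.seed)
    evals, record = rg.run_cv_regression(
        cleaned.values, cleaned.speed, roster, k=config.folds,
        m=config.n_selected_features, seed=config.seed)
    best = rg.select_best_regression(evals)
    stability = rg.stability_report(record, cleaned.values, cleaned.speed)
    stability.to_csv(outdir / "stability.tsv", sep="\t", index=False)
    _plot_scatter(cleaned.speed.to_numpy(),
                  evals[best].predictions.to_numpy(),
                  outdir / "speed_scatter.png")
    report = {
        "best_model": best,
        "models": {n: dict(mape=e.mape, pearson_r=e.pearson_r)
                   for n, e in evals.items()},
        "stable_features": stability.to_dict(orient="records"),
    }
    path = outdir / "regression_report.json"
    path.write_text(json.dumps(report, indent=1, sort_keys=True))
    _record_files(outdir, "regress", [path, outdir / "stability.tsv"])
    log.info("regress: best=%s MAPE=%.2f%% r=%.2f", best, evals[best].mape,
             evals[best].pearson_r)
    return path


def run_pipeline(config: PipelineConfig, outdir) -> dict[str, Path]:
    """Full deterministic run; returns the report paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    simulate_stage(config, outdir)
    extract_stage(config, outdir)
    out["features"] = features_stage(config, outdir)
    if config.run_classification:
        out["classification"] = classify_stage(config, outdir)
    if config.run_regression:
        out["regression"] = regress_stage(config, outdir)
    return out


# --------------------------------------------------------------------------
# cohort-in-memory helper (no files)
# --------------------------------------------------------------------------

def extract_cohort_features(cohort: sim.Cohort,
                            config: Optional[ev.ExtractionConfig] = None
                            ) -> ft.FeatureMatrix:
    """Trace extraction + aggregation for an in-memory cohort."""
    config = config or ev.ExtractionConfig()
    rows, ids, labels, speeds = [], [], [], []
    for subj in cohort.subjects:
        test_values = {
            "vergence": ft.trial_table_values(
                ev.extract_test_trials(subj.traces["vergence"], config)),
            "saccade": ft.trial_table_values(
                ev.extract_test_trials(subj.traces["saccade"], config)),
            "reading": ft.reading_values(
                ev.compute_reading_descriptors(subj.traces["reading"],
                                               config)),
        }
        rows.append(ft.aggregate_subject(test_values))
        ids.append(subj.subject_id)
        labels.append(subj.group)
        speeds.append(subj.reading_speed)
    return ft.build_feature_matrix(rows, ids, labels, speeds)


# --------------------------------------------------------------------------
# plots
# --------------------------------------------------------------------------

def _plot_permutation(res: clf.PermutationResult, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(res.permuted_accuracies, bins=20, color="steelblue", alpha=0.8)
    ax.axvline(res.observed_accuracy, color="red", lw=2,
               label=f"observed {res.observed_accuracy:.1f}%")
    ax.set_xlabel("permuted mean CV accuracy (%)")
    ax.set_ylabel("count")
    ax.set_title(f"{res.model}: p = {res.p_value:.3f}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_scatter(y: np.ndarray, pred: np.ndarray, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(y, pred, s=18, alpha=0.7)
    lims = [min(y.min(), pred.min()), max(y.max(), pred.max())]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("measured reading speed (words/min)")
    ax.set_ylabel("predicted reading speed (words/min)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
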
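"""Plain-text file formats: traces, event sidecars, feature matrices,
cohort manifests.

All files are UTF-8, tab-delimited with a one-line header and dot-decimal
numbers, independent of locale.  ``write`` then ``read`` is the identity
on valid objects (floats are serialized with round-trip precision).
Malformed input raises :class:`ParseError` naming the offending line.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .simulate import BinocularTrace

__all__ = [
    "ParseError",
    "write_trace",
    "read_trace",
    "write_feature_matrix",
    "read_feature_matrix",
    "file_checksum",
]

_FLOAT_FMT = "%.17g"  # round-trip precision for float64


class ParseError(ValueError):
    """Malformed file content; carries the 1-based line number."""

    def __init__(self, path, line_no: int, message: str) -> None:
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


# --------------------------------------------------------------------------
# traces
# --------------------------------------------------------------------------

def write_trace(path, trace: BinocularTrace) -> Path:
    """Trace as TSV (time_s, left_deg, right_deg) plus an ``.events.tsv``
    sidecar (onset_s, event_kind)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["time_s", "left_deg", "right_deg"])
        for t, l, r in zip(trace.time, trace.left, trace.right):
            w.writerow([_fmt(t), _fmt(l), _fmt(r)])
    with _events_path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["onset_s", "event_kind"])
        for onset, kind in trace.events:
            w.writerow([_fmt(onset), kind])
    return path


def _events_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".events.tsv")


def _read_rows(path: Path, expected_header: list[str]):
    with Path(path).open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(path, 1, "empty file") from None
        if header != expected_header:
            raise ParseError(path, 1,
                             f"expected header {expected_header}, got {header}")
        for line_no, row in enumerate(reader, start=2):
            if len(row) != len(expected_header):
                raise ParseError(path, line_no,
                                 f"expected {len(expected_header)} fields, "
                                 f"got {len(row)}")
            yield line_no, row


def read_trace(path, rate: float = 200.0) -> BinocularTrace:
    """Read a trace + events sidecar written by :func:`write_trace`."""
    path = Path(path)
    times, lefts, rights = [], [], []
    for line_no, row in _read_rows(path, ["time_s", "left_deg", "right_deg"]):
        try:
            times.append(float(row[0]))
            lefts.append(float(row[1]))
            rights.append(float(row[2]))
        except ValueError:
            raise ParseError(path, line_no, f"non-numeric value in {row}") \
                from None
    events = []
    ev_path = _events_path(path)
    if ev_path.exists():
        for line_no, row in _read_rows(ev_path, ["onset_s", "event_kind"]):
            try:
                events.append((float(row[0]), row[1]))
            except ValueError:
                raise ParseError(ev_path, line_no, "non-numeric onset") \
                    from None
    time = np.asarray(times)
    if len(time) > 1:
        rate = float(1.0 / np.median(np.diff(time)))
    return BinocularTrace(time=time, left=np.asarray(lefts),
                          right=np.asarray(rights), rate=rate, events=events)


# --------------------------------------------------------------------------
# feature matrices
# --------------------------------------------------------------------------

def write_feature_matrix(path, fm: FeatureMatrix) -> Path:
    """Feature matrix as TSV (subject_id, label, reading_speed_wpm,
    features...) plus a ``.mask.tsv`` sidecar of 0/1 aberrant flags."""
    path = Path(path)
    cols = fm.feature_names
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["subject_id", "label", "reading_speed_wpm"] + cols)
        for sid in fm.values.index:
            w.writerow([sid, fm.labels[sid], _fmt(fm.speed[sid])]
                       + [_fmt(v) for v in fm.values.loc[sid]])
    with _mask_path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["subject_id"] + cols)
        for sid in fm.mask.index:
            w.writerow([sid] + [int(v) for v in fm.mask.loc[sid]])
    return path


def _mask_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".mask.tsv")


def read_feature_matrix(path) -> FeatureMatrix:
    """Read a matrix + mask sidecar written by :func:`write_feature_matrix`.

    A matrix with zero subject rows raises :class:`ParseError`.
    """
    path = Path(path)
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(path, 1, "empty file") from None
        fixed = ["subject_id", "label", "reading_speed_wpm"]
        if header[:3] != fixed:
            raise ParseError(path, 1, f"header must start with {fixed}")
        cols = header[3:]
        ids, labels, speeds, values = [], [], [], []
        for line_no, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ParseError(path, line_no,
                                 f"expected {len(header)} fields, got {len(row)}")
            ids.append(row[0])
            labels.append(row[1])
            try:
                speeds.append(float(row[2]))
                values.append([float(v) for v in row[3:]])
            except ValueError:
                raise ParseError(path, line_no, "non-numeric value") from None
    if not ids:
        raise ParseError(path, 2, "matrix contains no subject rows")
    vdf = pd.DataFrame(np.asarray(values, dtype=float).reshape(len(ids), -1),
                       index=ids, columns=cols)
    mask = pd.DataFrame(False, index=ids, columns=cols)
    mpath = _mask_path(path)
    if mpath.exists():
        rows = {}
        for line_no, row in _read_rows(mpath, ["subject_id"] + cols):
            rows[row[0]] = [bool(int(v)) for v in row[1:]]
        for sid in ids:
            if sid in rows:
                mask.loc[sid] = rows[sid]
    return FeatureMatrix(values=vdf, mask=mask,
                         labels=pd.Series(labels, index=ids),
                         speed=pd.Series(speeds, index=ids, dtype=float))


# --------------------------------------------------------------------------
# checksums (run manifests)
# --------------------------------------------------------------------------

def file_checksum(path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
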
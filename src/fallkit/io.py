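"""Delimited-text readers and writers for recordings, annotations, segments,
feature tables and evaluation reports.

All formats are plain text for inspectability.  A recording is a CSV with
columns ``time_s, ax_g, ay_g, az_g``; its annotations live in a sibling
``<stem>_annotations.csv`` with columns ``label, time_s``.  Values are
written with 9 significant digits.  Externally supplied recordings in the
same layout can be loaded with an optional label map that sends arbitrary
annotation vocabularies (e.g. named fall subtypes) onto the 7 study classes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import EvaluationReport, FeatureDataset
from .segmentation import EventSegment, TriaxialRecording
from .simulate import CLASS_LABELS, AnnotatedRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_study",
    "load_external_recordings",
    "write_segments",
    "read_segments",
    "write_features",
    "read_features",
    "write_report",
    "read_report",
]

_FLOAT_FMT = "%.9g"
_RECORDING_COLUMNS = ["time_s", "ax_g", "ay_g", "az_g"]


def write_recording(annotated: AnnotatedRecording, directory, stem: str) -> tuple[Path, Path]:
    """Write one recording/annotation file pair; returns the two paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rec = annotated.recording
    t = np.arange(rec.n_samples) / rec.fs
    frame = pd.DataFrame(
        np.column_stack([t, rec.data]), columns=_RECORDING_COLUMNS
    )
    rec_path = directory / f"{stem}.csv"
    frame.to_csv(rec_path, index=False, float_format=_FLOAT_FMT)
    ann_path = directory / f"{stem}_annotations.csv"
    ann = pd.DataFrame(annotated.annotations, columns=["label", "time_s"])
    ann.to_csv(ann_path, index=False, float_format=_FLOAT_FMT)
    return rec_path, ann_path


def _infer_fs(times: np.ndarray, path) -> float:
    dt = np.diff(times)
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    return float(1.0 / np.median(dt))


def read_recording(
    recording_path,
    annotations_path=None,
    subject_id: str | None = None,
    sampling_rate: float | None = None,
    label_map: dict[str, str] | None = None,
) -> AnnotatedRecording:
    """Load one recording/annotation pair written in this package's format.

    ``label_map`` translates annotation labels (e.g. fall subtype names)
    onto the 7 study classes; labels already in the class set pass through.
    """
    recording_path = Path(recording_path)
    frame = pd.read_csv(recording_path)
    missing = [c for c in _RECORDING_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{recording_path}: missing columns {missing}")
    data = frame[_RECORDING_COLUMNS[1:]].to_numpy(dtype=float)
    lengths = {frame[c].notna().sum() for c in _RECORDING_COLUMNS[1:]}
    if len(lengths) != 1 or not np.all(np.isfinite(data)):
        raise ValueError(
            f"{recording_path}: axis channels have unequal lengths or missing values"
        )
    fs = sampling_rate or _infer_fs(frame["time_s"].to_numpy(dtype=float), recording_path)
    if annotations_path is None:
        annotations_path = recording_path.with_name(
            recording_path.stem + "_annotations.csv"
        )
    annotations_path = Path(annotations_path)
    if not annotations_path.exists():
        raise FileNotFoundError(f"missing annotation file {annotations_path}")
    ann = pd.read_csv(annotations_path)
    if not {"label", "time_s"} <= set(ann.columns):
        raise ValueError(f"{annotations_path}: needs columns label,time_s")
    annotations = []
    for row_number, row in enumerate(ann.itertuples(index=False), start=2):
        label = str(row.label)
        if label_map and label in label_map:
            label = label_map[label]
        if label not in CLASS_LABELS:
            raise ValueError(
                f"{annotations_path} row {row_number}: unknown label {row.label!r} "
                "(provide a label map onto the 7 study classes)"
            )
        annotations.append((label, float(row.time_s)))
    recording = TriaxialRecording(
        subject_id=subject_id or recording_path.stem, fs=fs, data=data
    )
    return AnnotatedRecording(recording=recording, annotations=tuple(annotations))


def write_study(recordings: list[AnnotatedRecording], directory) -> list[Path]:
    """Write one file pair per subject; returns the recording paths."""
    paths = []
    for annotated in recordings:
        rec_path, _ = write_recording(
            annotated, directory, annotated.recording.subject_id
        )
        paths.append(rec_path)
    return paths


def load_external_recordings(
    directory,
    sampling_rate: float | None = None,
    label_map: dict[str, str] | None = None,
) -> list[AnnotatedRecording]:
    """Load every recording/annotation pair found under a directory.

    Pairs are identified by the ``<stem>.csv`` / ``<stem>_annotations.csv``
    convention, sorted by stem.
    """
    directory = Path(directory)
    ann_files = sorted(directory.glob("*_annotations.csv"))
    if not ann_files:
        raise FileNotFoundError(f"no *_annotations.csv files under {directory}")
    recordings = []
    for ann_path in ann_files:
        stem = ann_path.name[: -len("_annotations.csv")]
        rec_path = directory / f"{stem}.csv"
        if not rec_path.exists():
            raise FileNotFoundError(f"annotations {ann_path} have no recording {rec_path}")
        recordings.append(
            read_recording(
                rec_path,
                ann_path,
                subject_id=stem,
                sampling_rate=sampling_rate,
                label_map=label_map,
            )
        )
    return recordings


def write_segments(segments: list[EventSegment], path) -> Path:
    """Write segments as one long-format CSV: subject, event_id, label, axis, k, value."""
    rows = []
    for event_id, seg in enumerate(segments):
        for axis_idx, axis in enumerate("xyz"):
            for k in range(seg.n_samples):
                rows.append(
                    (seg.subject_id, event_id, seg.label, seg.fs, axis, k, seg.data[k, axis_idx])
                )
    frame = pd.DataFrame(
        rows, columns=["subject", "event_id", "label", "fs", "axis", "k", "value"]
    )
    path = Path(path)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_segments(path) -> list[EventSegment]:
    """Load segments from the long-format CSV written by :func:`write_segments`."""
    frame = pd.read_csv(path)
    segments = []
    for (_, event_id), group in frame.groupby(["subject", "event_id"], sort=False):
        pivot = group.pivot(index="k", columns="axis", values="value").sort_index()
        data = pivot[["x", "y", "z"]].to_numpy(dtype=float)
        first = group.iloc[0]
        segments.append(
            EventSegment(
                subject_id=str(first["subject"]),
                label=str(first["label"]),
                fs=float(first["fs"]),
                data=data,
            )
        )
    return segments


def write_features(dataset: FeatureDataset, path) -> Path:
    """Write a feature table: subject and label columns then one column per feature."""
    frame = pd.DataFrame(dataset.X, columns=list(dataset.feature_names))
    frame.insert(0, "label", dataset.labels)
    frame.insert(0, "subject", dataset.subjects)
    path = Path(path)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_features(path) -> FeatureDataset:
    frame = pd.read_csv(path)
    if not {"subject", "label"} <= set(frame.columns):
        raise ValueError(f"{path}: feature table needs subject and label columns")
    names = [c for c in frame.columns if c not in ("subject", "label")]
    return FeatureDataset(
        X=frame[names].to_numpy(dtype=float),
        labels=frame["label"].to_numpy(),
        subjects=frame["subject"].to_numpy(),
        feature_names=tuple(names),
    )


def write_report(report: EvaluationReport, path) -> Path:
    """Write an evaluation report as JSON (metrics, folds, pooled confusion)."""
    payload = {
        "model": report.model_spec.family,
        "accuracy_pct": 100 * report.accuracy,
        "macro_f1_pct": 100 * report.macro_f1,
        "fold_subjects": list(report.fold_subjects),
        "fold_accuracy": list(report.fold_accuracy),
        "fold_macro_f1": list(report.fold_macro_f1),
        "confusion_labels": list(report.confusion.labels),
        "confusion_counts": report.confusion.counts.tolist(),
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_report(path) -> dict:
    with open(path) as handle:
        return json.load(handle)


def render_report(payload: dict) -> str:
    """Human-readable rendering of a report written by :func:`write_report`."""
    lines = [
        f"model: {payload['model']}",
        f"accuracy: {payload['accuracy_pct']:.2f}%",
        f"class-averaged F1: {payload['macro_f1_pct']:.2f}%",
        "",
        "pooled confusion matrix (rows = true, columns = predicted):",
    ]
    frame = pd.DataFrame(
        payload["confusion_counts"],
        index=payload["confusion_labels"],
        columns=payload["confusion_labels"],
    )
    lines.append(frame.to_string())
    return "\n".join(lines)
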
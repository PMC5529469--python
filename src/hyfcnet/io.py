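"""Cohort and matrix I/O.

Subjects live as delimited text (CSV/TSV): rows are time points,
columns are ROIs, the first row holds ROI labels.  A cohort manifest is
a CSV with columns ``subject_id``, ``path`` (relative to the manifest)
and binary ``label``; an optional ``tr_seconds`` column overrides the
default repetition time.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ManifestError
from .networks import ConnectivityMatrix, SubjectTimeSeries

__all__ = [
    "read_subject",
    "read_cohort",
    "write_cohort",
    "write_matrix",
    "read_matrix",
]


def read_subject(
    path: str | os.PathLike,
    *,
    subject_id: str | None = None,
    tr_seconds: float = 3.0,
) -> SubjectTimeSeries:
    """Read one subject's time-series CSV/TSV (header row = ROI labels)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep)
    return SubjectTimeSeries(
        frame.to_numpy(dtype=float),
        [str(c) for c in frame.columns],
        subject_id=subject_id or path.stem,
        tr_seconds=tr_seconds,
    )


def read_cohort(
    manifest_path: str | os.PathLike, *, tr_seconds: float = 3.0
) -> tuple[list[SubjectTimeSeries], np.ndarray]:
    """Read all subjects listed in a manifest, in manifest order.

    Validates that every subject has the same ROI labels in the same
    order and that labels are binary 0/1.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ManifestError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "path", "label"}
    missing = required - set(manifest.columns)
    if missing:
        raise ManifestError(f"manifest missing column(s): {sorted(missing)}")
    if not set(manifest["label"].unique()) <= {0, 1}:
        raise ManifestError(
            f"labels must be binary 0/1, got {sorted(manifest['label'].unique())}"
        )
    root = manifest_path.parent
    subjects: list[SubjectTimeSeries] = []
    for row in manifest.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = root / path
        if not path.exists():
            raise ManifestError(f"subject {row.subject_id!r}: file not found: {path}")
        tr = float(getattr(row, "tr_seconds", tr_seconds))
        subjects.append(read_subject(path, subject_id=str(row.subject_id), tr_seconds=tr))
    first = subjects[0]
    for ts in subjects[1:]:
        if ts.roi_labels != first.roi_labels:
            raise ManifestError(
                f"subject {ts.subject_id!r}: ROI labels differ from {first.subject_id!r}"
            )
        if ts.n_timepoints != first.n_timepoints:
            raise ManifestError(
                f"subject {ts.subject_id!r}: {ts.n_timepoints} time points, "
                f"expected {first.n_timepoints}"
            )
    return subjects, manifest["label"].to_numpy(dtype=int)


def write_cohort(
    subjects: Sequence[SubjectTimeSeries],
    labels: Sequence[int],
    out_dir: str | os.PathLike,
) -> Path:
    """Write per-subject CSVs plus ``manifest.csv``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts, label in zip(subjects, labels):
        fname = f"{ts.subject_id}.csv"
        pd.DataFrame(ts.data, columns=ts.roi_labels).to_csv(out / fname, index=False)
        rows.append(
            {
                "subject_id": ts.subject_id,
                "path": fname,
                "label": int(label),
                "tr_seconds": ts.tr_seconds,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def write_matrix(
    matrix: ConnectivityMatrix | np.ndarray,
    path: str | os.PathLike,
    *,
    roi_labels: Sequence[str] | None = None,
) -> None:
    """Write an R×R matrix as CSV with ROI labels as header/index."""
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    r = values.shape[0]
    labels = list(roi_labels) if roi_labels else [f"ROI{i + 1:03d}" for i in range(r)]
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path)


def read_matrix(path: str | os.PathLike) -> np.ndarray:
    """Read an R×R CSV written by :func:`write_matrix`."""
    return pd.read_csv(path, index_col=0).to_numpy(dtype=float)
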
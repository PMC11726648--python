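"""Readers and writers for the pipeline's tabular interchange formats.

All stages communicate through plain CSV: wide thickness / z-score matrices
(``subject_id, patch_0001, ...``), demographics, a long clinical table
(``subject_id, visit, measure, value``), tidy per-patch statistics, and
plain-text patch sets (see :mod:`mosaicmap.roi`).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import patch_labels

PATCH_COLUMN_RE = re.compile(r"^patch_(\d+)$")

DEMOGRAPHICS_COLUMNS = ("subject_id", "age", "sex", "handedness", "symptom_duration")
CLINICAL_COLUMNS = ("subject_id", "visit", "measure", "value")


class SchemaError(ValueError):
    """Raised when a table violates its schema, naming the offending cell."""


def _check_patch_columns(columns: list[str], path: Path) -> None:
    if not columns:
        raise SchemaError(f"{path}: no patch columns")
    numbers = []
    for col in columns:
        m = PATCH_COLUMN_RE.match(col)
        if not m:
            raise SchemaError(f"{path}: column {col!r} is not a patch_NNNN label")
        numbers.append(int(m.group(1)))
    expected = list(range(1, len(columns) + 1))
    if numbers != expected:
        missing = sorted(set(expected) - set(numbers))
        raise SchemaError(
            f"{path}: patch columns are not contiguous 1..{len(columns)}"
            + (f"; first gap at patch {missing[0]}" if missing else "")
        )


def _read_matrix(path: str | Path, require_positive: bool) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.columns[0] != "subject_id":
        raise SchemaError(f"{path}: first column must be 'subject_id'")
    patch_cols = list(frame.columns[1:])
    _check_patch_columns(patch_cols, path)
    ids = frame["subject_id"].astype(str)
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise SchemaError(f"{path}: duplicate subject id {dup.iloc[0]!r}")
    values = frame[patch_cols].to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise SchemaError(f"{path}: missing/non-finite value at subject "
                          f"{ids.iloc[r]!r}, column {patch_cols[c]!r}")
    if require_positive and (values <= 0).any():
        r, c = np.argwhere(values <= 0)[0]
        raise SchemaError(f"{path}: non-positive thickness at subject "
                          f"{ids.iloc[r]!r}, column {patch_cols[c]!r}")
    frame["subject_id"] = ids
    return frame


def read_thickness(path: str | Path) -> pd.DataFrame:
    """Read and validate a wide thickness matrix (strictly positive, complete)."""
    return _read_matrix(path, require_positive=True)


def read_z_matrix(path: str | Path) -> pd.DataFrame:
    """Read a wide z-score matrix (same layout, values unconstrained)."""
    return _read_matrix(path, require_positive=False)


def write_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a wide subject x patch matrix as CSV."""
    frame.to_csv(path, index=False)


write_thickness = write_matrix


def read_demographics(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in DEMOGRAPHICS_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing demographics columns {missing}")
    frame["subject_id"] = frame["subject_id"].astype(str)
    if (frame["age"] <= 0).any():
        bad = frame.loc[frame["age"] <= 0, "subject_id"].iloc[0]
        raise SchemaError(f"{path}: non-positive age for subject {bad!r}")
    return frame


def write_demographics(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing clinical columns {missing}")
    frame["subject_id"] = frame["subject_id"].astype(str)
    return frame


def write_clinical(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)
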
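"""Reading and writing of localization tables and sidecar files.

The canonical on-disk format is a plain CSV with header
``cell_id,track_id,frame,x_um,y_um`` — one row per detected molecule per
frame, coordinates in micrometres, frames as 0-based integers. This is the
dialect emitted by the synthetic generator and the dialect any external
tracker export must be mapped to.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("cell_id", "track_id", "frame", "x_um", "y_um")

GROUND_TRUTH_COLUMNS = ("track_id", "true_state", "nanodomain_id", "compartment_id")

#: fixed float formatting so that identical data always serializes byte-identically
FLOAT_FORMAT = "%.9g"


class TableFormatError(ValueError):
    """A localization table does not conform to the expected dialect."""


def read_localization_table(path: str | Path, unit_hint: str = "um") -> pd.DataFrame:
    """Read and validate a localization table.

    Parameters
    ----------
    path:
        CSV file with at least the columns ``cell_id, track_id, frame, x_um, y_um``.
    unit_hint:
        ``"um"`` (native) or ``"nm"``; nm coordinates are divided by 1000 on read.

    Returns
    -------
    DataFrame sorted by (cell_id, track_id, frame). Rows with non-finite
    coordinates are dropped with a counted warning.
    """
    if unit_hint not in ("um", "nm"):
        raise ValueError(f"unit_hint must be 'um' or 'nm', got {unit_hint!r}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing mandatory column(s) {missing}")
    try:
        df["frame"] = df["frame"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"{path}: frame column is not integer-valued") from exc
    for col in ("x_um", "y_um"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    finite = np.isfinite(df["x_um"].to_numpy()) & np.isfinite(df["y_um"].to_numpy())
    n_bad = int((~finite).sum())
    if n_bad:
        warnings.warn(f"{path}: dropped {n_bad} row(s) with non-finite coordinates")
        df = df.loc[finite]
    if unit_hint == "nm":
        df = df.assign(x_um=df["x_um"] / 1000.0, y_um=df["y_um"] / 1000.0)
    # mixed id dtypes (e.g. int and str track ids in one file) are rejected
    for col in ("cell_id", "track_id"):
        kinds = {type(v) for v in df[col].head(1000)}
        if len(kinds) > 1:
            raise TableFormatError(f"{path}: mixed types in column {col}: {kinds}")
    return df.sort_values(["cell_id", "track_id", "frame"], kind="stable").reset_index(
        drop=True
    )


def write_localization_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a localization table in the canonical dialect (deterministic bytes)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"cannot write table, missing column(s) {missing}")
    cols = list(REQUIRED_COLUMNS) + [c for c in df.columns if c not in REQUIRED_COLUMNS]
    df[cols].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_ground_truth(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GROUND_TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: ground-truth file missing column(s) {missing}")
    return df


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
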
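"""Cohort table and configuration I/O.

Cohort CSV schema (fixed header names, documented order): ``subject_id``,
``cohort``, ``abeta``, ``time_months``, ``event``, then one column per
gray-matter region (normalized volume fraction). Times are months since the
MCI visit; ``event`` is progression to AD; a missing amyloid value is an
empty field and is excluded from quartile computation downstream.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

META_COLUMNS = ["subject_id", "cohort", "abeta", "time_months", "event"]


def region_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks required columns: {missing}")
    ordered = table[META_COLUMNS + region_columns(table)]
    ordered.to_csv(path, index=False)


def read_cohort(path: str | Path, known_regions: list[str] | None = None) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    regions = region_columns(table)
    if known_regions is not None:
        unknown = [c for c in regions if c not in known_regions]
        if unknown:
            logger.warning("unknown columns in cohort file: %s", unknown)
    for col in regions + ["time_months"]:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = values.isna() & table[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric value in column {col!r} at row {int(np.flatnonzero(bad)[0])}"
            )
        table[col] = values
    table["abeta"] = pd.to_numeric(table["abeta"], errors="coerce")
    table["event"] = table["event"].astype(bool)
    if table["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id values")
    return table


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path, required: tuple = ()) -> dict:
    config = json.loads(Path(path).read_text())
    missing = [k for k in required if k not in config]
    if missing:
        raise ValueError(f"config is missing required keys: {missing}")
    return config


def save_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=_default, sort_keys=True))


def write_volume_nifti(voxels: np.ndarray, path: str | Path) -> None:
    """Write a 3D volume as NIfTI-1 with an identity affine."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(voxels, dtype=np.float32), affine=np.eye(4))
    nib.save(img, str(path))
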
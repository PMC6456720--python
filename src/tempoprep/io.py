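"""Delimited-text I/O for trial tables and sidecar files.

The trial CSV schema (UTF-8, header row) is::

    subject_id, group, session, block, duration_level, variability_level,
    tp_rank, foreperiod_ms, stimulus, response, rt_ms, valid

Times are integer-rounded milliseconds at the file boundary; missing RTs
(no response) are empty fields.  ``write_trials`` then ``read_trials`` is a
round-trip identity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import TRIAL_COLUMNS

__all__ = ["read_trials", "write_trials", "write_ground_truth", "read_ground_truth"]


def write_trials(trials: pd.DataFrame, path) -> None:
    """Serialize a trial table, rounding times to integer milliseconds."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    out = trials[TRIAL_COLUMNS].copy()
    out["foreperiod_ms"] = np.round(out["foreperiod_ms"]).astype(int)
    out["rt_ms"] = out["rt_ms"].round().astype("Int64")  # nullable: NONE trials
    out["valid"] = out["valid"].astype(bool)
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV; errors cite the offending column/row."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in raw.columns]
    unknown = [c for c in raw.columns if c not in TRIAL_COLUMNS]
    if missing or unknown:
        raise ValueError(
            f"trial CSV schema mismatch: missing columns {missing}, unknown columns {unknown}"
        )
    if raw.empty:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    out = raw.copy()
    for col in ("session", "block", "tp_rank", "foreperiod_ms"):
        out[col] = _to_number(raw[col], col, integer=True)
    rt = pd.array([None] * len(raw), dtype="Int64")
    for i, val in enumerate(raw["rt_ms"]):
        if val == "":
            continue
        try:
            rt[i] = round(float(val))
        except ValueError:
            raise ValueError(f"non-numeric rt_ms {val!r} at row {i + 2}") from None
    out["rt_ms"] = rt
    out["valid"] = raw["valid"].str.lower().isin(("true", "1"))
    return out[TRIAL_COLUMNS]


def _to_number(col: pd.Series, name: str, integer: bool = False) -> pd.Series:
    try:
        num = pd.to_numeric(col)
    except ValueError:
        bad = pd.to_numeric(col, errors="coerce")
        row = int(np.flatnonzero(bad.isna())[0]) + 2  # +1 header, +1 one-based
        raise ValueError(f"non-numeric {name} {col.iloc[row - 2]!r} at row {row}") from None
    return num.astype(int) if integer else num.astype(float)


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)


def read_ground_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path)
    expected = {"subject_id", "group", "parameter", "value"}
    if set(truth.columns) != expected:
        raise ValueError(f"ground-truth CSV must have columns {sorted(expected)}")
    return truth
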
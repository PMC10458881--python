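"""On-disk formats.

Profiles travel as long-format CSV with header ``test_id,time_min,dissolved_pct``;
designs as CSV with header ``test_id,group,pressure_mbar,timing_min``; class
labels as JSON records.  Readers validate eagerly and report offending row
numbers (1-based, counting the header as row 1).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import DesignMatrix
from .exceptions import FormatError
from .protocol import ClassLabel, DissolutionProfile, make_protocol

PROFILE_COLUMNS = ["test_id", "time_min", "dissolved_pct"]
DESIGN_COLUMNS = ["test_id", "group", "pressure_mbar", "timing_min"]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty (expected header {','.join(required)})")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def _require_numeric(df: pd.DataFrame, path, columns: list[str]) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            rows = [int(i) + 2 for i in bad[:5]]
            raise FormatError(f"{path}: non-numeric {col!r} values at rows {rows}")
        if df[col].isna().any():
            rows = [int(i) + 2 for i in df.index[df[col].isna()][:5]]
            raise FormatError(f"{path}: missing {col!r} values at rows {rows}")
        df[col] = coerced
    return df


def read_profiles(path) -> list[DissolutionProfile]:
    """Read a long-format profile CSV into per-test profiles, sorted by time.

    Raises FormatError on missing columns, non-numeric cells, or duplicate
    (test_id, time) pairs, naming the offending rows.
    """
    df = _read_csv(path, PROFILE_COLUMNS)
    if df.empty:
        return []
    df = _require_numeric(df, path, ["time_min", "dissolved_pct"])
    dup = df.duplicated(subset=["test_id", "time_min"], keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup][:5]]
        raise FormatError(f"{path}: duplicate (test_id, time_min) records at rows {rows}")
    profiles = []
    for tid, grp in df.groupby("test_id", sort=False):
        grp = grp.sort_values("time_min")
        profiles.append(
            DissolutionProfile(
                str(tid),
                grp["time_min"].to_numpy(dtype=float),
                grp["dissolved_pct"].to_numpy(dtype=float),
            )
        )
    return profiles


def write_profiles(profiles: Sequence[DissolutionProfile], path) -> None:
    rows = []
    for prof in profiles:
        for tm, dv in zip(prof.times, prof.dissolved):
            rows.append({"test_id": prof.test_id, "time_min": tm, "dissolved_pct": dv})
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


def read_design(path) -> DesignMatrix:
    df = _read_csv(path, DESIGN_COLUMNS)
    df = _require_numeric(df, path, ["pressure_mbar", "timing_min"])
    runs = tuple(
        make_protocol(str(r.test_id), float(r.pressure_mbar), float(r.timing_min), group=str(r.group))
        for r in df.itertuples()
    )
    return DesignMatrix(runs)


def write_design(design: DesignMatrix, path) -> None:
    design.frame.to_csv(path, index=False)


def read_labels(path) -> list[ClassLabel]:
    with open(path) as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise FormatError(f"{path}: expected a JSON array of label records")
    return [ClassLabel(str(r["test_id"]), str(r["state"])) for r in records]


def write_labels(labels: Iterable[ClassLabel], path) -> None:
    with open(path, "w") as fh:
        json.dump([{"test_id": l.test_id, "state": l.state} for l in labels], fh, indent=1)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
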
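"""CSV readers and writers for the pipeline's tabular artifacts.

All tables are UTF-8 CSV with a header row; money is in decimal dollars
(two fraction digits by construction), times in seconds, missing values
as empty fields.  Every writer has a reader that reproduces the
in-memory value.
"""

from __future__ import annotations

import os
import tempfile

import numpy as np
import pandas as pd

from .cohort import RECORD_COLUMNS, SCRTrace
from .task import CHOICE_SET_COLUMNS

__all__ = [
    "write_trials",
    "read_trials",
    "write_behavior",
    "read_behavior",
    "write_trace",
    "read_trace",
    "write_table",
    "read_table",
]


def _atomic_to_csv(df: pd.DataFrame, path: str) -> None:
    """Write via a temp file + rename so failures never leave partial CSVs."""
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _split_by_subject(df: pd.DataFrame) -> dict:
    return {s: g.drop(columns="subject").reset_index(drop=True)
            for s, g in df.groupby("subject", sort=True)}


def write_trials(path: str, choice_sets: dict) -> None:
    parts = []
    for s in sorted(choice_sets):
        part = choice_sets[s].copy()
        part.insert(0, "subject", s)
        parts.append(part)
    _atomic_to_csv(pd.concat(parts, ignore_index=True), path)


def read_trials(path: str) -> dict:
    df = pd.read_csv(path)
    missing = set(["subject", *CHOICE_SET_COLUMNS]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trial columns {sorted(missing)}")
    return _split_by_subject(df)


def write_behavior(path: str, records: dict) -> None:
    parts = []
    for s in sorted(records):
        part = records[s].copy()
        part.insert(0, "subject", s)
        parts.append(part)
    _atomic_to_csv(pd.concat(parts, ignore_index=True), path)


def read_behavior(path: str) -> dict:
    df = pd.read_csv(path)
    missing = set(["subject", *RECORD_COLUMNS]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing behavior columns {sorted(missing)}")
    df["missed"] = df["missed"].astype(bool)
    return _split_by_subject(df)


def write_trace(trace_path: str, events_path: str, trace: SCRTrace) -> None:
    """Trace CSV (time s, conductance µS) plus an event table CSV."""
    t = np.arange(len(trace.values)) / trace.fs
    _atomic_to_csv(
        pd.DataFrame({"time": t, "conductance": trace.values}), trace_path
    )
    _atomic_to_csv(trace.events, events_path)


def read_trace(trace_path: str, events_path: str) -> SCRTrace:
    df = pd.read_csv(trace_path)
    if not {"time", "conductance"} <= set(df.columns):
        raise ValueError(f"{trace_path}: expected time and conductance columns")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{trace_path}: trace too short to infer sampling rate")
    fs = 1.0 / float(np.median(np.diff(t)))
    events = pd.read_csv(events_path)
    return SCRTrace(
        fs=round(fs, 6),
        values=df["conductance"].to_numpy(dtype=float),
        events=events,
    )


def write_table(path: str, df: pd.DataFrame) -> None:
    _atomic_to_csv(df, path)


def read_table(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return pd.read_csv(path)
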
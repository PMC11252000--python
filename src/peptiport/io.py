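"""Delimited-text readers/writers for the versioned trace and table schemas.

Trace files are long-format CSV with columns (time_s, channel, value) plus a
sidecar event table (label, start_s, end_s). All writers round values to a
fixed per-column decimal precision so that re-reading is lossless at the
declared precision and outputs diff cleanly. Schema version: 1.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .assay_analysis import AssayTrace, TraceEvent

SCHEMA_VERSION = 1

#: decimal places per column family
_PRECISION = {"time_s": 3, "value": 6, "start_s": 3, "end_s": 3}


def write_trace(trace: AssayTrace, prefix: Path | str) -> list[Path]:
    """Write ``<prefix>.data.csv``, ``<prefix>.events.csv``, ``<prefix>.meta.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    for channel, values in trace.channels.items():
        frames.append(pd.DataFrame({
            "time_s": np.round(trace.time_s, _PRECISION["time_s"]),
            "channel": channel,
            "value": np.round(values, _PRECISION["value"]),
        }))
    data_path = prefix.with_suffix(".data.csv")
    pd.concat(frames, ignore_index=True).to_csv(data_path, index=False)

    events_path = prefix.with_suffix(".events.csv")
    pd.DataFrame([
        {"label": ev.label,
         "start_s": round(ev.start_s, _PRECISION["start_s"]),
         "end_s": round(ev.end_s, _PRECISION["end_s"])}
        for ev in trace.events
    ]).to_csv(events_path, index=False)

    meta_path = prefix.with_suffix(".meta.json")
    meta = {"schema_version": SCHEMA_VERSION, "metadata": trace.metadata}
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return [data_path, events_path, meta_path]


def read_trace(prefix: Path | str) -> AssayTrace:
    """Read a trace written by :func:`write_trace`."""
    prefix = Path(prefix)
    data = pd.read_csv(prefix.with_suffix(".data.csv"))
    for col in ("time_s", "channel", "value"):
        if col not in data.columns:
            raise ValueError(f"trace data file missing column {col!r}")
    channels = {}
    time = None
    for channel, grp in data.groupby("channel", sort=False):
        grp = grp.sort_values("time_s")
        if time is None:
            time = grp["time_s"].to_numpy()
        channels[channel] = grp["value"].to_numpy()

    events_file = prefix.with_suffix(".events.csv")
    events = []
    if events_file.exists():
        for _, row in pd.read_csv(events_file).iterrows():
            events.append(TraceEvent(row["label"], float(row["start_s"]), float(row["end_s"])))

    meta_file = prefix.with_suffix(".meta.json")
    metadata = {}
    if meta_file.exists():
        payload = json.loads(meta_file.read_text())
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported trace schema version {payload.get('schema_version')}")
        metadata = payload.get("metadata", {})
    return AssayTrace(time, channels, events, metadata)


def write_table(df: pd.DataFrame, path: Path | str, decimals: int = 6) -> Path:
    """Write a result table as CSV with fixed float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.round(decimals).to_csv(path, index=False)
    return path


def read_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(Path(path))
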
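"""Plain-text I/O: trace CSV + YAML sidecar, beat tables, event JSON lines."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .delineate import EcgTrace
from .patterns import RhythmEvent

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_beats_csv", "read_beats_csv",
    "write_events_jsonl", "read_events_jsonl",
]


def write_trace_csv(trace: EcgTrace, path) -> None:
    """Two-column CSV (time_s, voltage_mV) plus a ``.yaml`` sidecar carrying
    the sampling rate, units and generator metadata."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.time_s(), "voltage_mV": trace.samples})
    df.to_csv(path, index=False, float_format="%.6f")
    meta = dict(fs_hz=float(trace.fs_hz), t0_s=float(trace.t0_s), units="mV")
    meta.update(trace.meta)
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_trace_csv(path) -> EcgTrace:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        fs = float(meta.pop("fs_hz"))
        t0 = float(meta.pop("t0_s", 0.0))
        meta.pop("units", None)
    else:
        # infer the rate from the time axis when no sidecar is present
        dt = np.median(np.diff(df["time_s"].to_numpy()))
        fs = float(np.round(1.0 / dt, 3))
        t0 = float(df["time_s"].iloc[0])
        meta = {}
    return EcgTrace(samples=df["voltage_mV"].to_numpy(dtype=float), fs_hz=fs, t0_s=t0, meta=meta)


def write_beats_csv(beats: pd.DataFrame, path) -> None:
    beats.to_csv(path, index=False)


def read_beats_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events_jsonl(events, path) -> None:
    """One JSON object per line: etype, start_beat, end_beat, n_vpb, onset_time_s."""
    with open(path, "w") as fh:
        for e in events:
            d = dataclasses.asdict(e) if dataclasses.is_dataclass(e) else dict(e)
            fh.write(json.dumps(d) + "\n")


def read_events_jsonl(path) -> list[RhythmEvent]:
    events = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                events.append(RhythmEvent(**json.loads(line)))
    return events
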
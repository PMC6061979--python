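"""Delimited-text trace files.

Traces are written as CSV with unit-annotated column names (time_ms, v_mV,
ca_mM, i_<channel>_mA_cm2, ...) preceded by '#'-prefixed metadata lines
holding a JSON document (protocol summary, dt, temperature, seed).  Columns
are identified by header name, so files with reordered columns read back
correctly; a round trip preserves values to float precision.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .cell import SimulationTrace

__all__ = ["write_trace", "read_trace"]


def write_trace(trace: SimulationTrace, path) -> None:
    """Write a trace as commented-header CSV."""
    frame = trace.to_frame()
    meta = {"sites": list(trace.sites), **_jsonable(trace.metadata)}
    with open(path, "w") as fh:
        fh.write("# detrusor-trace v1\n")
        fh.write("# " + json.dumps(meta) + "\n")
        frame.to_csv(fh, index=False)


def read_trace(path) -> SimulationTrace:
    """Read a trace written by :func:`write_trace`."""
    meta = {}
    with open(path) as fh:
        header_lines = 0
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            payload = line[1:].strip()
            if payload.startswith("{"):
                meta = json.loads(payload)
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ValueError(f"malformed trace file {path}: {exc}") from exc
    if "time_ms" not in frame.columns:
        raise ValueError(
            f"{path}: missing required column 'time_ms' "
            f"(line {header_lines + 1})"
        )
    sites = tuple(meta.pop("sites", ()) or ("soma",))
    v_cols = [c for c in frame.columns if c == "v_mV" or c.startswith("v_")]
    ca_cols = [c for c in frame.columns if c == "ca_mM" or c.startswith("ca_")]
    cur_cols = [c for c in frame.columns if c.startswith("i_")]
    if not v_cols:
        raise ValueError(f"{path}: no voltage column found")
    v = frame[v_cols].to_numpy()
    v = v[:, 0] if v.shape[1] == 1 else v
    ca = None
    if ca_cols:
        ca = frame[ca_cols].to_numpy()
        ca = ca[:, 0] if ca.shape[1] == 1 else ca
    currents = {
        c[len("i_") : -len("_mA_cm2")]: frame[c].to_numpy() for c in cur_cols
    }
    return SimulationTrace(
        time=frame["time_ms"].to_numpy(),
        v=v,
        currents=currents,
        ca=ca,
        sites=sites,
        metadata=meta,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
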
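"""Trace TSV + JSON-sidecar serialization.

A trace is stored as a two-column, tab-separated file (``time_s``,
``value``) next to a JSON sidecar (same stem, ``.json``) that carries
the authoritative grid (so round-trips are bit-exact), the signal kind,
the stimulus event and free-form metadata. Values are printed with 17
significant digits, which reconstructs every IEEE double exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .model import ModelTrace, TimeGrid
from .traceproc import Trace

__all__ = ["write_trace", "read_trace", "sidecar_path"]


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_trace(trace, path) -> Path:
    """Write a :class:`Trace` or :class:`ModelTrace` as TSV + JSON sidecar."""
    path = Path(path)
    times = trace.grid.times
    with open(path, "w") as fh:
        fh.write("time_s\tvalue\n")
        for t, v in zip(times, trace.values):
            fh.write(f"{t:.17g}\t{v:.17g}\n")
    meta = {
        "t_start": trace.grid.t_start,
        "dt": trace.grid.dt,
        "n_points": trace.grid.n_points,
    }
    if isinstance(trace, ModelTrace):
        meta["kind"] = trace.kind
        meta["params"] = dict(trace.params)
    else:
        meta["signal_kind"] = trace.signal_kind
        stim = trace.stimulus
        meta["stimulus"] = stim.to_dict() if hasattr(stim, "to_dict") else stim
        meta["meta"] = dict(trace.meta)
    with open(sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_trace(path) -> Trace:
    """Read a TSV trace, validating the time column.

    The sidecar's grid is authoritative (bit-exact round-trip); when the
    sidecar is missing, the grid is reconstructed from the time column
    and defaults are assumed with a warning. A non-uniform or shuffled
    time column raises :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    if list(frame.columns[:2]) != ["time_s", "value"]:
        raise FormatError(
            f"{path}: expected header 'time_s\\tvalue', got {list(frame.columns)}"
        )
    times = frame["time_s"].to_numpy(dtype=float)
    values = frame["value"].to_numpy(dtype=float)
    if times.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    diffs = np.diff(times)
    dt = float(np.median(diffs))
    bad = np.nonzero(~np.isclose(diffs, dt, rtol=1e-6, atol=1e-12))[0]
    if dt <= 0 or bad.size:
        line = int(bad[0]) + 3 if bad.size else 2  # header + 1-based + offset
        raise FormatError(
            f"{path}: non-uniform or non-increasing time column at line {line}"
        )

    side = sidecar_path(path)
    if side.exists():
        with open(side) as fh:
            meta = json.load(fh)
        grid = TimeGrid(meta["t_start"], meta["dt"], meta["n_points"])
        if grid.n_points != times.size:
            raise FormatError(
                f"{path}: sidecar n_points {grid.n_points} != rows {times.size}"
            )
        extra = dict(meta.get("meta", {}))
        if "kind" in meta:  # model trace: keep its identity in metadata
            extra.setdefault("kind", meta["kind"])
            extra.setdefault("params", meta.get("params", {}))
            return Trace(grid, values, "current", None, extra)
        return Trace(grid, values, meta.get("signal_kind", "current"),
                     meta.get("stimulus"), extra)
    warnings.warn(
        f"{path}: sidecar {side.name} missing; assuming current trace with "
        "grid taken from the time column",
        stacklevel=2,
    )
    return Trace(TimeGrid(float(times[0]), dt, times.size), values, "current")
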
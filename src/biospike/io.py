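"""File I/O, configuration and seed plumbing.

Traces travel as 2-column CSV (``time_s``, ``dff`` or ``f_norm``) with an
optional JSON sidecar recording rate, units, seeds and parameter
provenance; spike trains as single-column text/CSV of seconds.  All times
are seconds and ΔF/F is dimensionless throughout the package.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cell import FluorescenceTrace, SpikeTrain

TRACE_COLUMNS = ("dff", "f_norm")


def read_trace(path) -> FluorescenceTrace:
    """Read a trace CSV; sampling must be uniform within 1e-6 relative."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise ValueError(f"{path}: empty or unparseable trace file") from e
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing 'time_s' header")
    ycol = next((c for c in TRACE_COLUMNS if c in df.columns), None)
    if ycol is None:
        raise ValueError(f"{path}: missing a 'dff' or 'f_norm' column")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    bad = np.where(np.abs(dt - dt[0]) > 1e-6 * max(abs(dt[0]), 1e-12))[0]
    if dt[0] <= 0 or bad.size:
        idx = int(bad[0] + 1) if bad.size else 1
        raise ValueError(f"{path}: non-uniform sampling at row {idx}")
    return FluorescenceTrace(t=t, dff=df[ycol].to_numpy(dtype=float),
                             rate=1.0 / dt[0])


def write_trace(trace: FluorescenceTrace, path, column: str = "dff",
                sidecar: dict | None = None) -> None:
    """Write a trace CSV at 9 significant digits (round-trip faithful)."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.t, column: trace.dff})
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {"rate_hz": trace.rate, "units": {"time": "s", column:
            "dimensionless"}}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1))


def read_spikes(path) -> SpikeTrain:
    """Read spike times (one per line or single-column CSV), seconds."""
    path = Path(path)
    raw = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if raw and not raw[0].replace(".", "").replace("-", "").replace(
            "e", "").replace("+", "").isdigit():
        raw = raw[1:]          # header line
    times = np.array([float(v) for v in raw])
    if (times < 0).any():
        raise ValueError(f"{path}: negative spike times")
    if np.unique(times).size != times.size:
        raise ValueError(f"{path}: duplicate spike times")
    if times.size > 1 and (np.diff(times) < 0).any():
        warnings.warn(f"{path}: unsorted spike times; sorting",
                      stacklevel=2)
        times = np.sort(times)
    return SpikeTrain(times)


def write_spikes(spikes: SpikeTrain, path) -> None:
    Path(path).write_text(
        "\n".join(f"{t:.9g}" for t in spikes.times) + "\n"
        if len(spikes) else "")


def load_groundtruth_epochs(directory):
    """Optional adapter for an external paired ground-truth dataset.

    Expects a directory of epochs, each a ``<name>.csv`` trace (time_s,
    dff) next to a ``<name>.spikes.txt`` spike list; returns a list of
    (FluorescenceTrace, SpikeTrain) pairs.  The dataset is not shipped:
    this adapter only reads a local copy if the user has one.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(
            f"ground-truth dataset directory {directory} not found; this "
            "adapter requires a local copy of an external benchmark "
            "dataset and is optional")
    pairs = []
    for tr_path in sorted(directory.glob("*.csv")):
        sp_path = tr_path.with_suffix("").with_suffix(".spikes.txt")
        if sp_path.exists():
            pairs.append((read_trace(tr_path), read_spikes(sp_path)))
    if not pairs:
        raise FileNotFoundError(
            f"no (<name>.csv, <name>.spikes.txt) pairs under {directory}")
    return pairs
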
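"""Readers and writers for the pipeline's file formats.

All files are plain CSV/JSON: acceleration as ``time,ax,ay,az``, context as
``start,end,terrain,environment,task[,notes]``, step tables as written by
:func:`write_step_table`.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    AccelRecording,
    ContextLabel,
    DataError,
    FormatError,
    validate_context_track,
)

log = logging.getLogger("freegait")

ACCEL_COLUMNS = ("time", "ax", "ay", "az")
CONTEXT_COLUMNS = ("start", "end", "terrain", "environment", "task")
STEP_COLUMNS = (
    "ic_time", "side", "step_time", "stance_time", "swing_time",
    "step_length", "step_velocity",
)


def read_accel_csv(
    path: Union[str, Path],
    units: str = "m_per_s2",
    fs: Union[float, str] = "infer",
) -> AccelRecording:
    """Read a ``time,ax,ay,az`` CSV into an :class:`AccelRecording`.

    With ``fs="infer"`` the sampling frequency is the reciprocal of the
    median inter-sample interval.  Small timing gaps are filled by linear
    interpolation onto the uniform grid; if more than 1% of samples are
    gap-filled a warning is logged (CWT differentiation assumes uniform
    sampling).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in ACCEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 rows")
    t = df["time"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        raise DataError(f"{path}: time column is not strictly increasing")
    dt = np.diff(t)
    if fs == "infer":
        fs_val = 1.0 / float(np.median(dt))
    else:
        fs_val = float(fs)
    nominal = 1.0 / fs_val
    grid = np.arange(t[0], t[-1] + nominal / 2, nominal)
    gappy = np.count_nonzero(dt > 1.5 * nominal)
    if gappy / len(dt) > 0.01:
        log.warning("%s: %d of %d intervals exceed 1.5x the nominal spacing", path, gappy, len(dt))
    axes = {}
    for c in ("ax", "ay", "az"):
        vals = df[c].to_numpy(dtype=float)
        if len(grid) != len(t) or not np.allclose(grid, t, atol=nominal * 0.01):
            vals = np.interp(grid, t, vals)
        axes[c] = vals
    return AccelRecording(start_time=float(t[0]), fs=fs_val, units=units, **axes)


def write_accel_csv(path: Union[str, Path], rec: AccelRecording) -> None:
    df = pd.DataFrame(
        {
            "time": rec.start_time + rec.t,
            "ax": rec.ax,
            "ay": rec.ay,
            "az": rec.az,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_context_csv(path: Union[str, Path]) -> list[ContextLabel]:
    """Read context labels; labels are returned sorted and overlap-checked."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in CONTEXT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    labels = [
        ContextLabel(
            start=float(r.start),
            end=float(r.end),
            terrain=str(r.terrain),
            environment=str(r.environment),
            task=str(r.task),
            notes=str(getattr(r, "notes", "") or ""),
        )
        for r in df.itertuples(index=False)
    ]
    return validate_context_track(labels)


def write_context_csv(path: Union[str, Path], labels: Sequence[ContextLabel]) -> None:
    df = pd.DataFrame(
        [
            {
                "start": lb.start,
                "end": lb.end,
                "terrain": lb.terrain,
                "environment": lb.environment,
                "task": lb.task,
                "notes": lb.notes,
            }
            for lb in labels
        ]
    )
    df.to_csv(path, index=False)


def write_step_table(path: Union[str, Path], table: pd.DataFrame) -> None:
    cols = [c for c in STEP_COLUMNS if c in table.columns]
    table.to_csv(path, index=False, columns=cols, float_format="%.9g")


def read_step_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in STEP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_events_csv(path: Union[str, Path], ev) -> None:
    """Write gait events as ``time,type,side`` rows (ICs then matched FCs)."""
    rows = [
        {"time": t, "type": "IC", "side": s}
        for t, s in zip(ev.ic_times, ev.sides)
    ]
    rows += [
        {"time": t, "type": "FC", "side": ""}
        for t in ev.fc_times
        if np.isfinite(t)
    ]
    df = pd.DataFrame(rows, columns=["time", "type", "side"])
    df.sort_values("time", kind="stable").to_csv(path, index=False, float_format="%.9g")


def write_cwt_csv(path: Union[str, Path], sig) -> None:
    """Dump the CWT signal chain (t, y_int, d1, d2) for plotting."""
    pd.DataFrame(
        {"t": sig.t, "y_int": sig.y_int, "d1": sig.d1, "d2": sig.d2}
    ).to_csv(path, index=False, float_format="%.9g")


def write_ground_truth_json(path: Union[str, Path], truth) -> None:
    payload = {
        "ic_times": list(map(float, truth.ic_times)),
        "fc_times": list(map(float, truth.fc_times)),
        "sides": list(truth.sides),
        "step_times": list(map(float, truth.step_times)),
        "step_lengths": list(map(float, truth.step_lengths)),
        "com_heights": list(map(float, truth.com_heights)),
        "n_steps": int(truth.n_steps),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_ground_truth_json(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())
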
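"""Per-step temporal and spatial gait characteristics.

Temporal characteristics follow the event-sequence definitions: step time is
IC-to-next-IC; stance is same-side IC-to-FC; swing is same-side FC-to-next-IC.
Spatial characteristics come from the inverted-pendulum model: the vertical
acceleration is doubly integrated to the CoM vertical excursion h per step,
and step length is ``2*sqrt(2*l*h - h**2)`` for leg length ``l``.  Undefined
values are NaN markers, never zeros, and are excluded from summaries.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, filtfilt

from .config import PipelineConfig
from .types import ComTrace, DataError, GaitEvents, VerticalSeries

STEP_CHARACTERISTICS = (
    "step_time", "stance_time", "swing_time", "step_length", "step_velocity",
)


def temporal_characteristics(ev: GaitEvents) -> pd.DataFrame:
    """Per-step step/stance/swing times from paired events.

    Row ``i`` is the step starting at ``ic_times[i]`` taken by side
    ``sides[i]``.  The toe-off of that foot is the FC matched to the *next*
    IC (``fc_times[i+1]``), so::

        step_time_i   = ic[i+1] - ic[i]
        stance_time_i = fc[i+1] - ic[i]
        swing_time_i  = ic[i+2] - fc[i+1]

    Rows lacking a component carry NaN.
    """
    ic = ev.ic_times
    fc = ev.fc_times
    sides = ev.sides
    n = len(ic)
    if n >= 2:
        pairs = zip(sides[:-1], sides[1:])
        if any(a == b for a, b in pairs):
            raise DataError("sides must strictly alternate")
    rows = []
    for i in range(n - 1):
        step_time = ic[i + 1] - ic[i]
        stance = fc[i + 1] - ic[i] if np.isfinite(fc[i + 1]) else np.nan
        if i + 2 < n and np.isfinite(fc[i + 1]):
            swing = ic[i + 2] - fc[i + 1]
        else:
            swing = np.nan
        rows.append(
            {
                "ic_time": ic[i],
                "side": sides[i],
                "step_time": step_time,
                "stance_time": stance,
                "swing_time": swing,
            }
        )
    df = pd.DataFrame(rows, columns=["ic_time", "side", "step_time", "stance_time", "swing_time"])
    return df


def com_vertical_displacement(
    v: VerticalSeries,
    ev: GaitEvents,
    highpass_hz: float = 0.5,
    min_step_samples: int = 5,
) -> ComTrace:
    """Per-step CoM vertical excursion by double integration of a_v.

    Velocity and displacement are zero-phase high-passed (4th-order
    Butterworth at ``highpass_hz``) to control integration drift; per step
    ``h`` is the max-min of the displacement over ``[IC_i, IC_{i+1})``.
    Steps shorter than ``min_step_samples`` get NaN.
    """
    fs = v.fs
    dt = 1.0 / fs
    b, a = butter(4, highpass_hz / (fs / 2), btype="highpass")
    vel = cumulative_trapezoid(v.a_v, dx=dt, initial=0.0)
    if np.ptp(vel) > 0:
        vel = filtfilt(b, a, vel)
    disp = cumulative_trapezoid(vel, dx=dt, initial=0.0)
    if np.ptp(disp) > 0:
        disp = filtfilt(b, a, disp)

    ic = ev.ic_times
    h = np.full(max(len(ic) - 1, 0), np.nan)
    t0 = v.t[0]
    for i in range(len(ic) - 1):
        j0 = int(round((ic[i] - t0) * fs))
        j1 = int(round((ic[i + 1] - t0) * fs))
        j0, j1 = max(j0, 0), min(j1, len(disp) - 1)
        if j1 - j0 + 1 >= min_step_samples:
            seg = disp[j0 : j1 + 1]
            h[i] = float(seg.max() - seg.min())
    return ComTrace(h=h, displacement=disp, t=v.t)


def step_lengths(trace: ComTrace, leg_length_m: float) -> np.ndarray:
    """Inverted-pendulum step length ``2*sqrt(2*l*h - h**2)`` per step.

    Steps with ``h >= l`` violate the geometry and are marked NaN.
    """
    if leg_length_m <= 0:
        raise DataError("leg length must be positive")
    h = trace.h
    out = np.full_like(h, np.nan)
    ok = np.isfinite(h) & (h < leg_length_m)
    out[ok] = 2.0 * np.sqrt(2.0 * leg_length_m * h[ok] - h[ok] ** 2)
    return out


def step_velocities(tbl: pd.DataFrame) -> pd.DataFrame:
    """Add ``step_velocity = step_length / step_time`` (NaN propagates)."""
    tbl = tbl.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        tbl["step_velocity"] = tbl["step_length"] / tbl["step_time"]
    return tbl


def compute_step_table(
    v: VerticalSeries,
    ev: GaitEvents,
    cfg: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Full per-step table: temporal + spatial characteristics."""
    cfg = cfg or PipelineConfig()
    tbl = temporal_characteristics(ev)
    trace = com_vertical_displacement(v, ev, highpass_hz=cfg.highpass_hz)
    tbl["step_length"] = step_lengths(trace, cfg.leg_length_m)
    return step_velocities(tbl)
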
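"""Walking-bout segmentation: upright + moving periods tiled into windows."""
from __future__ import annotations

import logging
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, filtfilt

from .config import PipelineConfig
from .types import (
    AccelRecording,
    AnalysisWindow,
    DataError,
    G,
    WalkingBout,
    convert_units,
)

log = logging.getLogger("freegait")


def _as_mps2(rec: AccelRecording) -> AccelRecording:
    return convert_units(rec, "m_per_s2")


def upright_mask(
    rec: AccelRecording,
    win_s: float = 2.0,
    tilt_max_deg: float = 45.0,
    vertical_axis: str = "az",
) -> np.ndarray:
    """True where the device is tilted less than ``tilt_max_deg`` from vertical.

    The nominally-vertical axis is low-passed below ``1/win_s`` Hz and
    compared against ``cos(tilt) * g``: an upright wearer keeps gravity on
    that axis, a lying wearer moves it to a horizontal axis.
    """
    rec = _as_mps2(rec)
    if rec.duration_s < win_s:
        raise DataError(f"recording shorter than the {win_s} s posture window")
    cutoff = 1.0 / win_s
    b, a = butter(2, cutoff / (rec.fs / 2), btype="lowpass")
    low = filtfilt(b, a, rec.axis(vertical_axis))
    return low > np.cos(np.deg2rad(tilt_max_deg)) * G


def movement_mask(
    rec: AccelRecording,
    win_s: float = 1.0,
    sd_thresh: float = 0.1,
) -> np.ndarray:
    """True where the sliding-window SD of |a| exceeds ``sd_thresh`` (m/s²)."""
    rec = _as_mps2(rec)
    if rec.duration_s < win_s:
        raise DataError(f"recording shorter than the {win_s} s movement window")
    mag = np.sqrt(rec.ax**2 + rec.ay**2 + rec.az**2)
    size = max(int(round(win_s * rec.fs)), 2)
    mean = uniform_filter1d(mag, size, mode="nearest")
    mean_sq = uniform_filter1d(mag**2, size, mode="nearest")
    sd = np.sqrt(np.clip(mean_sq - mean**2, 0.0, None))
    return sd > sd_thresh


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) index runs of True."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def extract_walking_bouts(
    rec: AccelRecording,
    cfg: Optional[PipelineConfig] = None,
    confirm: Optional[Callable[[AccelRecording, WalkingBout], bool]] = None,
    recording_id: str = "rec",
) -> list[WalkingBout]:
    """Maximal upright-and-moving runs, gap-merged and length-filtered.

    Gaps up to ``cfg.gap_merge_s`` are merged, runs shorter than
    ``cfg.min_bout_s`` dropped.  When ``cfg.confirm_gait`` is set, each
    candidate is kept only if event detection finds at least 4 alternating
    initial contacts inside it (``confirm`` overrides the default check).
    """
    cfg = cfg or PipelineConfig()
    mask = upright_mask(
        rec, cfg.upright_win_s, cfg.tilt_max_deg, cfg.vertical_axis
    ) & movement_mask(rec, cfg.move_win_s, cfg.move_sd_thresh)

    fs = rec.fs
    runs = _runs(mask)
    merged: list[list[int]] = []
    gap = int(round(cfg.gap_merge_s * fs))
    for start, stop in runs:
        if merged and start - merged[-1][1] <= gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    bouts = [
        WalkingBout(start=s / fs, end=e / fs, recording_id=recording_id)
        for s, e in merged
        if (e - s) / fs >= cfg.min_bout_s
    ]

    if confirm is None and cfg.confirm_gait:
        from .events import bout_has_gait  # local import avoids a cycle

        confirm = lambda r, b: bout_has_gait(r, b, cfg)  # noqa: E731
    if confirm is not None:
        kept = []
        for b in bouts:
            if confirm(rec, b):
                kept.append(b)
            else:
                log.info("bout [%.1f, %.1f) rejected: no confirmed gait", b.start, b.end)
        bouts = kept
    return bouts


def window_bouts(
    bouts: Sequence[WalkingBout], window_s: float = 30.0
) -> list[AnalysisWindow]:
    """Tile each bout into consecutive ``window_s`` windows from its start.

    A tail shorter than ``window_s`` is discarded.
    """
    if window_s <= 0:
        raise DataError("window_s must be positive")
    windows = []
    for i, b in enumerate(bouts):
        k = 0
        while b.start + (k + 1) * window_s <= b.end + 1e-9:
            windows.append(
                AnalysisWindow(
                    bout_id=f"{b.recording_id}-b{i}",
                    start=b.start + k * window_s,
                    end=b.start + (k + 1) * window_s,
                    window_s=window_s,
                )
            )
            k += 1
    return windows
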
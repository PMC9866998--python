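"""Context-label merging, stratified tables, and the video review manifest.

Context is consumed as externally supplied interval labels (in the source
workflow these come from wearable-camera review); this module attaches them
to analysis windows, builds per-terrain characteristic tables, and ranks
anomalous windows for targeted video inspection.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .summary import DOMAIN_ROWS, WindowSummary
from .types import ContextLabel, validate_context_track

#: Terrain column order for stratified tables (lab first, stairs last,
#: anything unrecognised alphabetical before "unknown").
TERRAIN_ORDER = ("lab", "asphalt", "asphalt_paving", "paving", "stairs_up", "stairs_down")
UNKNOWN = "unknown"


@dataclass
class ContextualWindow:
    """A WindowSummary with its dominant context and anomaly statistics."""

    summary: WindowSummary
    terrain: str = UNKNOWN
    environment: str = UNKNOWN
    task: str = UNKNOWN
    coverage: float = 0.0
    anomaly_count: int = 0
    max_score: float = 0.0

    @property
    def start(self) -> float:
        return self.summary.window.start

    @property
    def end(self) -> float:
        return self.summary.window.end


def align_context(
    summaries: Sequence[WindowSummary],
    track: Sequence[ContextLabel],
    min_coverage: float = 0.5,
) -> list[ContextualWindow]:
    """Assign each window the label with the largest temporal overlap.

    Coverage is overlap / window length; below ``min_coverage`` the window
    is labelled "unknown".  Ties are broken in favour of the later-starting
    label (deterministic).
    """
    track = validate_context_track(track)
    out = []
    for ws in summaries:
        w = ws.window
        best, best_ov = None, 0.0
        for lb in track:  # sorted by start; later label wins ties via >=
            ov = max(0.0, min(w.end, lb.end) - max(w.start, lb.start))
            if ov > 0 and ov >= best_ov:
                best, best_ov = lb, ov
        cov = best_ov / w.duration_s if w.duration_s > 0 else 0.0
        if best is not None and cov >= min_coverage:
            cw = ContextualWindow(
                summary=ws, terrain=best.terrain, environment=best.environment,
                task=best.task, coverage=cov,
            )
        else:
            cw = ContextualWindow(summary=ws, coverage=cov)
        out.append(cw)
    return out


def attach_anomalies(
    cws: Sequence[ContextualWindow],
    flags: Sequence[tuple[int, str, float]],
    step_ic_times: np.ndarray,
) -> None:
    """Count flagged steps per window (in place) given step-level flags."""
    for cw in cws:
        scores = [
            s for idx, _, s in flags
            if cw.start <= step_ic_times[idx] < cw.end
        ]
        cw.anomaly_count = len(scores)
        cw.max_score = max(scores, default=0.0)


def _terrain_sort_key(name: str):
    if name in TERRAIN_ORDER:
        return (0, TERRAIN_ORDER.index(name), name)
    if name == UNKNOWN:
        return (2, 0, name)
    return (1, 0, name)


def contextual_summary(cws: Sequence[ContextualWindow]) -> pd.DataFrame:
    """Per-terrain means of the 13 domain characteristics.

    Columns are terrains in canonical order; a final ``n_windows`` row
    counts the windows contributing to each column.
    """
    if not cws:
        raise ValueError("need at least one contextual window")
    terrains = sorted({cw.terrain for cw in cws}, key=_terrain_sort_key)
    data: dict[str, list] = {}
    for terr in terrains:
        group = [cw for cw in cws if cw.terrain == terr]
        col = []
        for dom, label, char, stat in DOMAIN_ROWS:
            vals = [cw.summary.get(char, stat) for cw in group]
            vals = [v for v in vals if np.isfinite(v)]
            col.append(float(np.mean(vals)) if vals else np.nan)
        col.append(len(group))
        data[terr] = col
    index = [label for _, label, _, _ in DOMAIN_ROWS] + ["n_windows"]
    df = pd.DataFrame(data, index=index)
    df.index.name = "characteristic"
    return df


def review_manifest(
    cws: Sequence[ContextualWindow],
    top_n: int = 10,
    video_offset_s: float = 0.0,
) -> pd.DataFrame:
    """Rank anomalous windows for targeted video review.

    Windows are ordered by anomaly count, then maximal anomaly score, then
    start time (a deterministic total order); only windows with at least one
    flagged step are emitted.  Timestamps carry ``video_offset_s`` so they
    land on the video timeline.
    """
    ranked = sorted(
        (cw for cw in cws if cw.anomaly_count > 0),
        key=lambda cw: (-cw.anomaly_count, -cw.max_score, cw.start),
    )[:top_n]
    rows = [
        {
            "start_s": cw.start + video_offset_s,
            "end_s": cw.end + video_offset_s,
            "reason": (
                f"{cw.anomaly_count} anomalous step(s), "
                f"max deviation {cw.max_score:.1f} robust SDs"
            ),
            "terrain": cw.terrain,
            "environment": cw.environment,
            "task": cw.task,
        }
        for cw in ranked
    ]
    return pd.DataFrame(
        rows, columns=["start_s", "end_s", "reason", "terrain", "environment", "task"]
    )
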
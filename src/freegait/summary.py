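"""Window-level summaries, four-domain stratification, anomaly flagging.

Each 30 s window is collapsed to mean / SD / asymmetry of the five step
characteristics; variability is the (sample) SD across detected steps in the
window and asymmetry is the absolute difference of left- and right-step
means, sides taken as every other step.  The 13 resulting quantities map
onto the four mobility domains: Pace, Rhythm, Variability, Asymmetry.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .characteristics import STEP_CHARACTERISTICS
from .config import PipelineConfig
from .types import AnalysisWindow

log = logging.getLogger("freegait")

#: (domain, characteristic, window statistic) rows of the four-domain model.
DOMAIN_ROWS = (
    ("Pace", "Mean step velocity (m/s)", "step_velocity", "mean"),
    ("Pace", "Mean step length (m)", "step_length", "mean"),
    ("Rhythm", "Mean step time (s)", "step_time", "mean"),
    ("Rhythm", "Mean swing time (s)", "swing_time", "mean"),
    ("Variability", "Step time variability (s)", "step_time", "sd"),
    ("Variability", "Stance time variability (s)", "stance_time", "sd"),
    ("Variability", "Swing time variability (s)", "swing_time", "sd"),
    ("Variability", "Step length variability (s)", "step_length", "sd"),
    ("Variability", "Step velocity variability (s)", "step_velocity", "sd"),
    ("Asymmetry", "Step time asymmetry (s)", "step_time", "asy"),
    ("Asymmetry", "Stance time asymmetry (s)", "stance_time", "asy"),
    ("Asymmetry", "Swing time asymmetry (s)", "swing_time", "asy"),
    ("Asymmetry", "Step length asymmetry (s)", "step_length", "asy"),
)


@dataclass
class WindowSummary:
    """Mean/SD/asymmetry of each characteristic within one window."""

    window: AnalysisWindow
    n_steps: int
    values: dict = field(default_factory=dict)  # (characteristic, stat) -> float

    def get(self, characteristic: str, stat: str) -> float:
        return self.values.get((characteristic, stat), np.nan)


def summarize_window(
    tbl: pd.DataFrame,
    window: AnalysisWindow,
    cfg: Optional[PipelineConfig] = None,
) -> Optional[WindowSummary]:
    """Collapse the steps whose IC lies in the window to mean/SD/asymmetry.

    Mean is the arithmetic mean over defined values, SD the sample standard
    deviation (ddof per config), and asymmetry ``|mean(L) - mean(R)|``.
    Windows with fewer than ``cfg.min_steps_per_window`` steps are dropped
    (returns None).
    """
    cfg = cfg or PipelineConfig()
    steps = tbl[(tbl["ic_time"] >= window.start) & (tbl["ic_time"] < window.end)]
    if len(steps) < cfg.min_steps_per_window:
        log.info(
            "window [%.1f, %.1f) dropped: %d steps < minimum %d",
            window.start, window.end, len(steps), cfg.min_steps_per_window,
        )
        return None
    values = {}
    for c in STEP_CHARACTERISTICS:
        x = steps[c].to_numpy(dtype=float)
        defined = x[np.isfinite(x)]
        values[(c, "mean")] = float(np.mean(defined)) if len(defined) else np.nan
        values[(c, "sd")] = (
            float(np.std(defined, ddof=cfg.sd_ddof)) if len(defined) > cfg.sd_ddof else np.nan
        )
        xl = steps.loc[steps["side"] == "L", c].to_numpy(dtype=float)
        xr = steps.loc[steps["side"] == "R", c].to_numpy(dtype=float)
        xl, xr = xl[np.isfinite(xl)], xr[np.isfinite(xr)]
        values[(c, "asy")] = (
            float(abs(np.mean(xl) - np.mean(xr))) if len(xl) and len(xr) else np.nan
        )
    return WindowSummary(window=window, n_steps=len(steps), values=values)


def stratify_domains(ws: WindowSummary) -> pd.DataFrame:
    """Deterministically map a WindowSummary onto the 13 four-domain rows."""
    rows = [
        {
            "domain": dom,
            "characteristic": label,
            "value": ws.get(char, stat),
        }
        for dom, label, char, stat in DOMAIN_ROWS
    ]
    return pd.DataFrame(rows, columns=["domain", "characteristic", "value"])


def flatten_domains(dt: pd.DataFrame) -> dict:
    """Inverse of stratify_domains: (characteristic, stat) -> value."""
    out = {}
    for (dom, label, char, stat), (_, row) in zip(DOMAIN_ROWS, dt.iterrows()):
        out[(char, stat)] = row["value"]
    return out


def flag_anomalies(
    tbl: pd.DataFrame,
    k: float = 3.0,
    characteristics=STEP_CHARACTERISTICS,
) -> list[tuple[int, str, float]]:
    """Flag steps deviating more than ``k`` robust SDs from the median.

    The scale is 1.4826 * MAD; when the MAD is zero but the data are not
    constant the scale falls back to 1.2533 * mean absolute deviation.
    Truly constant characteristics produce no flags.  Scores are the
    deviation/scale ratio, invariant to unit rescaling.
    """
    flags = []
    for c in characteristics:
        if c not in tbl.columns:
            continue
        x = tbl[c].to_numpy(dtype=float)
        idx = np.flatnonzero(np.isfinite(x))
        if len(idx) < 3:
            continue
        vals = x[idx]
        med = np.median(vals)
        dev = np.abs(vals - med)
        scale = 1.4826 * np.median(dev)
        if scale == 0:
            scale = 1.2533 * float(np.mean(dev))
        if scale == 0:
            continue
        scores = dev / scale
        for j in np.flatnonzero(scores > k):
            flags.append((int(idx[j]), c, float(scores[j])))
    return sorted(flags, key=lambda f: (f[0], f[1]))
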
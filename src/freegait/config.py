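"""Pipeline configuration with JSON round-trip.

Every threshold the source method leaves open is collected here so a run is
fully reproducible from its serialized config.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from .types import ConfigError


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis pipeline.

    Attributes
    ----------
    fs_expected : float
        Nominal sampling frequency, Hz.
    window_s : float
        Analysis window length, seconds (30 s windows of ~57 steps).
    leg_length_m : float
        Pendulum length for the step-length model; must be supplied per
        subject, default 0.9 m.
    scale_policy : str | float
        ``"auto"`` tunes the Gaussian CWT scale to the dominant step
        frequency in 0.5-3 Hz; a float fixes the target frequency in Hz.
    upright_win_s : float
        Low-pass window for posture; cutoff is ``1/upright_win_s`` Hz.
    tilt_max_deg : float
        Maximum tilt from vertical still counted as upright.
    move_win_s, move_sd_thresh : float
        Sliding-SD movement detector: window (s) and threshold (m/s²).
    gap_merge_s, min_bout_s : float
        Bout assembly: gaps up to ``gap_merge_s`` merged, bouts shorter
        than ``min_bout_s`` dropped.
    bout_pad_s : float
        Context padding around a bout for edge-safe event detection.
    edge_exclude_s : float
        Events this close to the padded-series edge are discarded.
    min_prominence_frac, min_separation_s : float
        Peak picking: prominence as a fraction of the robust signal
        amplitude, and minimum event separation.
    pair_lo_frac, pair_hi_frac : float
        IC->FC matching window as fractions of the median step time.
    first_side : str
        Side assigned to the first detected IC ("L" or "R"); asymmetry is
        invariant to this choice.
    min_steps_per_window : int
        Windows with fewer steps are dropped from summaries.
    anomaly_k : float
        Median/MAD outlier threshold for step anomaly flagging.
    sd_ddof : int
        1 = sample SD (default), 0 = population SD.
    highpass_hz : float
        Zero-phase high-pass cutoff used to control integration drift.
    vertical_axis : str
        Device axis nominally vertical when upright ("ax"/"ay"/"az").
    confirm_gait : bool
        Keep only bouts in which event detection finds >= 4 alternating ICs.
    video_offset_s : float
        Constant offset added to manifest timestamps to align with a video
        timeline.
    seed : int
        Seed for any stochastic stage (none in the core pipeline; recorded
        for provenance).
    """

    fs_expected: float = 100.0
    window_s: float = 30.0
    leg_length_m: float = 0.9
    scale_policy: Union[str, float] = "auto"
    upright_win_s: float = 2.0
    tilt_max_deg: float = 45.0
    move_win_s: float = 1.0
    move_sd_thresh: float = 0.1
    gap_merge_s: float = 2.0
    min_bout_s: float = 10.0
    bout_pad_s: float = 1.0
    edge_exclude_s: float = 0.5
    min_prominence_frac: float = 0.2
    min_separation_s: float = 0.25
    pair_lo_frac: float = 0.1
    pair_hi_frac: float = 0.9
    first_side: str = "L"
    min_steps_per_window: int = 10
    anomaly_k: float = 3.0
    sd_ddof: int = 1
    highpass_hz: float = 0.5
    vertical_axis: str = "az"
    confirm_gait: bool = True
    video_offset_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "fs_expected", "window_s", "leg_length_m", "upright_win_s",
            "tilt_max_deg", "move_win_s", "move_sd_thresh", "gap_merge_s",
            "min_bout_s", "min_separation_s", "anomaly_k", "highpass_hz",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.min_prominence_frac < 0 or self.bout_pad_s < 0 or self.edge_exclude_s < 0:
            raise ConfigError("fractions and paddings must be non-negative")
        if not (0 <= self.pair_lo_frac < self.pair_hi_frac <= 1):
            raise ConfigError("pairing window fractions must satisfy 0 <= lo < hi <= 1")
        if self.first_side not in ("L", "R"):
            raise ConfigError("first_side must be 'L' or 'R'")
        if self.sd_ddof not in (0, 1):
            raise ConfigError("sd_ddof must be 0 or 1")
        if self.vertical_axis not in ("ax", "ay", "az"):
            raise ConfigError("vertical_axis must be one of ax/ay/az")
        if isinstance(self.scale_policy, str):
            if self.scale_policy != "auto":
                raise ConfigError("scale_policy must be 'auto' or a frequency in Hz")
        elif self.scale_policy <= 0:
            raise ConfigError("fixed scale frequency must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))
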
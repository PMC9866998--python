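"""Shared domain types for the gait-analysis pipeline.

Time convention: seconds relative to the recording start, as floats; all
intervals are half-open ``[start, end)``.  Standard gravity is fixed at
9.80665 m/s² for unit conversion.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Standard gravity used for g <-> m/s² conversion (exact by convention).
G = 9.80665

VALID_UNITS = ("g", "m_per_s2")
VALID_ENVIRONMENTS = ("indoor", "outdoor")
VALID_TASKS = ("single", "dual")


class FreegaitError(Exception):
    """Base class for all package errors."""


class FormatError(FreegaitError):
    """A file does not have the expected columns/layout."""


class DataError(FreegaitError):
    """File content violates a data invariant (e.g. non-monotone time)."""


class ConfigError(FreegaitError):
    """Invalid configuration value."""


class ParameterError(FreegaitError):
    """Invalid simulation or algorithm parameter."""


class OrientationError(FreegaitError):
    """No accelerometer axis is close enough to gravity (device worn wrong)."""


class ValidationError(FreegaitError):
    """Context labels or derived structures violate their invariants."""


@dataclass
class AccelRecording:
    """Timestamped tri-axial acceleration.

    Parameters
    ----------
    start_time
        UTC seconds of the first sample (0.0 for synthetic data).
    fs
        Sampling frequency in Hz.
    ax, ay, az
        Equal-length acceleration arrays in ``units``.
    units
        Either ``"g"`` or ``"m_per_s2"``.
    """

    start_time: float
    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    units: str = "m_per_s2"

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.fs <= 0:
            raise ConfigError(f"sampling frequency must be positive, got {self.fs}")
        n = len(self.ax)
        if n < 1 or len(self.ay) != n or len(self.az) != n:
            raise DataError("axis arrays must be non-empty and of equal length")
        if self.units not in VALID_UNITS:
            raise ConfigError(f"unknown unit tag {self.units!r}; expected one of {VALID_UNITS}")
        for name, arr in (("ax", self.ax), ("ay", self.ay), ("az", self.az)):
            if not np.all(np.isfinite(arr)):
                raise DataError(f"non-finite values in {name}")

    @property
    def n_samples(self) -> int:
        return len(self.az)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds relative to the recording start."""
        return np.arange(self.n_samples) / self.fs

    def axis(self, name: str) -> np.ndarray:
        try:
            return {"ax": self.ax, "ay": self.ay, "az": self.az}[name]
        except KeyError:
            raise ConfigError(f"unknown axis {name!r}") from None


def convert_units(rec: AccelRecording, target: str) -> AccelRecording:
    """Convert a recording between g and m/s² (factor 9.80665, exact).

    Idempotent when ``target`` equals the current units.
    """
    if target not in VALID_UNITS:
        raise ConfigError(f"unknown unit tag {target!r}; expected one of {VALID_UNITS}")
    if target == rec.units:
        return rec
    factor = G if rec.units == "g" else 1.0 / G
    return replace(
        rec,
        ax=rec.ax * factor,
        ay=rec.ay * factor,
        az=rec.az * factor,
        units=target,
    )


@dataclass
class VerticalSeries:
    """Gravity-removed vertical acceleration over (a padding of) one bout.

    ``a_v`` is signed positive in the direction of gravity (downward), the
    convention under which initial contacts appear as minima of the
    CWT-differentiated signal.  ``core_start``/``core_end`` delimit the bout
    proper when the series includes padding for edge-safe event detection.
    """

    t: np.ndarray
    a_v: np.ndarray
    core_start: Optional[float] = None
    core_end: Optional[float] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a_v = np.asarray(self.a_v, dtype=float)
        if len(self.t) != len(self.a_v):
            raise DataError("t and a_v must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise DataError("t must be strictly increasing")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class GaitEvents:
    """Ordered initial/final contact times with alternating side labels.

    ``fc_times`` is aligned with ``ic_times``: ``fc_times[i]`` is the final
    contact detected 0.1–0.9 median-step-times after ``ic_times[i]`` (NaN when
    unmatched).  Physiologically that contact is the toe-off of the foot that
    struck at ``ic_times[i-1]``; the temporal-characteristic stage re-indexes
    accordingly.
    """

    ic_times: np.ndarray
    fc_times: np.ndarray
    sides: np.ndarray
    source_bout: Optional[str] = None
    n_unmatched_ic: int = 0
    n_unmatched_fc: int = 0
    low_quality: bool = False

    def __post_init__(self) -> None:
        self.ic_times = np.asarray(self.ic_times, dtype=float)
        self.fc_times = np.asarray(self.fc_times, dtype=float)
        self.sides = np.asarray(self.sides, dtype=object)
        if len(self.fc_times) != len(self.ic_times) or len(self.sides) != len(self.ic_times):
            raise DataError("ic_times, fc_times and sides must be aligned")
        if len(self.ic_times) > 1:
            if not np.all(np.diff(self.ic_times) > 0):
                raise DataError("ic_times must be strictly increasing")
            fc = self.fc_times[np.isfinite(self.fc_times)]
            if len(fc) > 1 and not np.all(np.diff(fc) > 0):
                raise DataError("fc_times must be strictly increasing")
        matched = np.isfinite(self.fc_times)
        if np.any(self.fc_times[matched] <= self.ic_times[matched]):
            raise DataError("each matched FC must follow its IC")

    @property
    def n_ic(self) -> int:
        return len(self.ic_times)


@dataclass
class ContextLabel:
    """One labelled interval of terrain / environment / task context."""

    start: float
    end: float
    terrain: str
    environment: str = "outdoor"
    task: str = "single"
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValidationError(f"label end ({self.end}) must exceed start ({self.start})")
        if self.environment not in VALID_ENVIRONMENTS:
            raise ValidationError(
                f"unknown environment {self.environment!r}; expected one of {VALID_ENVIRONMENTS}"
            )
        if self.task not in VALID_TASKS:
            raise ValidationError(f"unknown task {self.task!r}; expected one of {VALID_TASKS}")


def validate_context_track(labels: Sequence[ContextLabel]) -> list[ContextLabel]:
    """Sort labels by start and reject overlapping pairs.

    Returns the sorted list; raises :class:`ValidationError` naming every
    offending pair if any two intervals overlap.
    """
    ordered = sorted(labels, key=lambda lb: (lb.start, lb.end))
    offenders = []
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            offenders.append((a, b))
    if offenders:
        msg = "; ".join(
            f"[{a.start}, {a.end}) {a.terrain} overlaps [{b.start}, {b.end}) {b.terrain}"
            for a, b in offenders
        )
        raise ValidationError(f"overlapping context labels: {msg}")
    return ordered


@dataclass
class WalkingBout:
    """Maximal upright-and-moving period confirmed to contain gait."""

    start: float
    end: float
    recording_id: str = ""

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise DataError("bout end must exceed start")

    @property
    def duration_s(self) -> float:
        return self.end - self.start


@dataclass
class AnalysisWindow:
    """One fixed-length analysis window tiled from a bout's start."""

    bout_id: str
    start: float
    end: float
    window_s: float = 30.0

    @property
    def duration_s(self) -> float:
        return self.end - self.start


@dataclass
class CwtSignals:
    """Signal chain of the CWT event detector.

    ``y_int`` is the detrended integral of a_v; ``d1`` its Gaussian-CWT
    differentiation (IC candidates = minima); ``d2`` the further
    differentiation (FC candidates = maxima).  ``scale`` is the Gaussian
    sigma in samples; ``f0`` the dominant step frequency it was tuned to.
    """

    t: np.ndarray
    y_int: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    scale: float
    f0: float
    fs: float
    core_start: Optional[float] = None
    core_end: Optional[float] = None

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.y_int) == len(self.d1) == len(self.d2) == n):
            raise DataError("all CWT chain arrays must share one length")
        if self.scale <= 0:
            raise ConfigError("CWT scale must be positive")


@dataclass
class ComTrace:
    """Per-step centre-of-mass vertical excursion from double integration."""

    h: np.ndarray                      # per-step max-min displacement (m), NaN if undefined
    displacement: np.ndarray           # full high-passed displacement series (m)
    t: np.ndarray                      # time base of `displacement`

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        finite = self.h[np.isfinite(self.h)]
        if np.any(finite < 0):
            raise DataError("CoM height change must be non-negative")
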
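"""Synthetic lumbar-accelerometer gait signals with known ground truth.

The generator builds the centre-of-mass (CoM) vertical trajectory of
inverted-pendulum walking: within each step the CoM vaults along a circular
arc of radius ``leg_length`` over a chord of length ``step_length``,
traversed at constant horizontal speed.  Consecutive arcs meet in a kink at
each initial contact (IC); the kink — the heel-strike velocity reversal —
is smoothed with a short Gaussian (``transition_sigma_s``), and the vertical
acceleration is the *exact* second derivative of that smoothed trajectory.
This keeps double integration and the pendulum inversion near-exact while
reproducing the strong, phase-locked heel-strike transient that real lumbar
signals carry at the step frequency.

The recorded vertical axis carries gravity plus the upward acceleration;
i.i.d. Gaussian sensor noise is added per axis.  Standing segments are
gravity-only; lying segments put gravity on a horizontal axis.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .types import (
    AccelRecording,
    ContextLabel,
    G,
    ParameterError,
)

#: Double-support duration (s) separating an IC from the contralateral
#: toe-off; 0.674 s stance minus 0.524 s step time in level-ground data.
DOUBLE_SUPPORT_S = 0.15

ACTIVITIES = ("stand", "lie", "walk")


@dataclass
class SimParams:
    """Simulation parameters; defaults are typical impaired level-ground walking.

    Step time and length default to the level-asphalt means (0.524 s,
    0.562 m); leg length defaults to 0.9 m, giving a geometric CoM excursion
    of ~4.5 cm per step.  ``noise_sd`` is broadband sensor noise; the
    default 0.05 m/s² is generous for a modern logging accelerometer
    (~0.01 m/s²) while staying below the 0.1 m/s² stillness threshold so
    that stationary postures remain classifiable; higher values model
    soft-tissue artefact.
    ``transition_sigma_s`` is the Gaussian width smoothing each heel-strike
    kink; larger values deepen the double-support dip of the trajectory and
    bias the pendulum inversion, so it is kept short (0.01 s).
    """

    duration_s: float = 30.0
    step_time_mean_l: float = 0.524
    step_time_mean_r: float = 0.524
    step_time_sd: float = 0.0
    step_length_mean_l: float = 0.562
    step_length_mean_r: float = 0.562
    leg_length_m: float = 0.9
    com_excursion_m: Optional[float] = None
    noise_sd: float = 0.05
    transition_sigma_s: float = 0.01
    first_side: str = "L"
    fs: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "duration_s", "step_time_mean_l", "step_time_mean_r",
            "step_length_mean_l", "step_length_mean_r", "leg_length_m",
            "transition_sigma_s", "fs",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if self.step_time_sd < 0 or self.noise_sd < 0:
            raise ParameterError("step_time_sd and noise_sd must be non-negative")
        for name in ("step_length_mean_l", "step_length_mean_r"):
            if getattr(self, name) >= 2 * self.leg_length_m:
                raise ParameterError(
                    f"{name} = {getattr(self, name)} violates pendulum geometry "
                    f"(must be < 2 x leg length = {2 * self.leg_length_m})"
                )
        if self.first_side not in ("L", "R"):
            raise ParameterError("first_side must be 'L' or 'R'")


@dataclass
class GroundTruth:
    """True events and per-step characteristics of a simulated recording."""

    ic_times: np.ndarray
    fc_times: np.ndarray
    sides: np.ndarray
    step_times: np.ndarray
    step_lengths: np.ndarray
    com_heights: np.ndarray

    @property
    def n_steps(self) -> int:
        return len(self.step_times)

    def shifted(self, offset: float) -> "GroundTruth":
        return replace(
            self,
            ic_times=self.ic_times + offset,
            fc_times=self.fc_times + offset,
        )


def _arc_height(u: np.ndarray, s: float, l: float) -> np.ndarray:
    """Pendulum arc height above the chord endpoints; u in [-s/2, s/2]."""
    return np.sqrt(l**2 - u**2) - np.sqrt(l**2 - (s / 2) ** 2)


def _draw_steps(params: SimParams, rng: np.random.Generator):
    """Draw IC times, sides, and per-step times/lengths filling duration_s."""
    min_step = 0.25
    ics = [0.0]
    sides: list[str] = []
    step_times: list[float] = []
    step_lengths: list[float] = []
    side = params.first_side
    while True:
        mean = params.step_time_mean_l if side == "L" else params.step_time_mean_r
        T = mean + (rng.normal(0.0, params.step_time_sd) if params.step_time_sd > 0 else 0.0)
        T = max(T, min_step)
        nxt = ics[-1] + T
        if nxt > params.duration_s + 1e-9:
            break
        ics.append(nxt)
        sides.append(side)
        step_times.append(T)
        step_lengths.append(
            params.step_length_mean_l if side == "L" else params.step_length_mean_r
        )
        side = "R" if side == "L" else "L"
    if len(ics) < 2:
        raise ParameterError("duration too short for a single step")
    return (
        np.asarray(ics), np.asarray(sides, dtype=object),
        np.asarray(step_times), np.asarray(step_lengths),
    )


def _com_trajectory(
    ics: np.ndarray,
    step_lengths: np.ndarray,
    params: SimParams,
    n: int,
) -> np.ndarray:
    """Kinked arc-chain CoM height sampled on the recording grid (m)."""
    dt = 1.0 / params.fs
    t = np.arange(n) * dt
    h = np.zeros(n)
    l = params.leg_length_m
    for i in range(len(ics) - 1):
        t0, t1 = ics[i], ics[i + 1]
        s = step_lengths[i]
        m = (t >= t0) & (t < t1)
        if not np.any(m):
            continue
        v = s / (t1 - t0)
        u = v * (t[m] - t0) - s / 2
        h[m] = _arc_height(np.clip(u, -s / 2, s / 2), s, l)
    if params.com_excursion_m is not None:
        peak = float(h.max())
        if peak > 0:
            h *= params.com_excursion_m / peak
    return h


def simulate_walk(params: SimParams) -> tuple[AccelRecording, GroundTruth]:
    """Simulate continuous walking with known events and characteristics.

    The returned vertical axis is ``g + d²h/dt²`` (upward positive reading)
    where ``h`` is the Gaussian-smoothed arc-chain CoM height; ground-truth
    ICs are the arc start instants.  With ``noise_sd = 0`` and equal sides
    the signal is periodic at the step time.
    """
    rng = np.random.default_rng(params.seed)
    ics, sides, step_times, step_lengths = _draw_steps(params, rng)
    n = int(round(params.duration_s * params.fs))
    dt = 1.0 / params.fs

    h_kinked = _com_trajectory(ics, step_lengths, params, n)
    sigma = params.transition_sigma_s * params.fs
    a_up = gaussian_filter1d(h_kinked, sigma, order=2, mode="nearest") / dt**2
    h_smooth = gaussian_filter1d(h_kinked, sigma, order=0, mode="nearest")

    com_heights = np.full(len(step_times), np.nan)
    for i in range(len(step_times)):
        i0 = int(round(ics[i] * params.fs))
        i1 = min(int(round(ics[i + 1] * params.fs)), n - 1)
        if i1 > i0:
            seg = h_smooth[i0 : i1 + 1]
            com_heights[i] = seg.max() - seg.min()

    ax = np.zeros(n)
    ay = np.zeros(n)
    az = G + a_up
    rec = AccelRecording(start_time=0.0, fs=params.fs, ax=ax, ay=ay, az=az)
    if params.noise_sd > 0:
        rec = add_sensor_noise(rec, params.noise_sd, seed=int(rng.integers(2**31)))

    fc_times = ics[1:] + DOUBLE_SUPPORT_S
    truth = GroundTruth(
        ic_times=ics,
        fc_times=fc_times[fc_times <= params.duration_s],
        sides=sides,
        step_times=step_times,
        step_lengths=step_lengths,
        com_heights=com_heights,
    )
    return rec, truth


def add_sensor_noise(rec: AccelRecording, noise_sd: float, seed: int = 0) -> AccelRecording:
    """Add i.i.d. Gaussian noise per axis; ``noise_sd = 0`` is the identity."""
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be non-negative, got {noise_sd}")
    if noise_sd == 0:
        return rec
    rng = np.random.default_rng(seed)
    return replace(
        rec,
        ax=rec.ax + rng.normal(0, noise_sd, rec.n_samples),
        ay=rec.ay + rng.normal(0, noise_sd, rec.n_samples),
        az=rec.az + rng.normal(0, noise_sd, rec.n_samples),
    )


ScheduleEntry = Union[tuple, list]


def _parse_entry(entry: ScheduleEntry):
    activity, duration = entry[0], float(entry[1])
    extra = dict(entry[2]) if len(entry) > 2 and entry[2] else {}
    if activity not in ACTIVITIES:
        raise ParameterError(f"unknown activity {activity!r}; expected one of {ACTIVITIES}")
    if duration <= 0:
        raise ParameterError("segment duration must be positive")
    return activity, duration, extra


def simulate_recording(
    schedule: Sequence[ScheduleEntry],
    params: SimParams,
    taper_s: float = 1.0,
) -> tuple[AccelRecording, GroundTruth, list[ContextLabel]]:
    """Simulate a schedule of ``(activity, duration_s[, overrides])`` segments.

    Activities are ``stand`` (upright, gravity on the vertical axis),
    ``lie`` (gravity on a horizontal axis) and ``walk``.  Gravity
    reorientations between postures are cosine-tapered over ``taper_s`` to
    avoid integrator shock; the walking dynamic itself starts at full
    amplitude (a first step is a real step).  An override dict per walk
    entry may adjust SimParams fields (e.g. ``step_time_sd``) and the
    context fields ``terrain``/``environment``/``task``.

    Ground-truth events exist only inside walk segments; the returned
    context track labels every segment.
    """
    if not schedule:
        raise ParameterError("schedule must be non-empty")
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    dt = 1.0 / fs

    baselines = {"stand": (0.0, 0.0, G), "lie": (G, 0.0, 0.0), "walk": (0.0, 0.0, G)}
    seg_arrays = []
    labels: list[ContextLabel] = []
    ic_all, fc_all, side_all = [], [], []
    st_all, sl_all, ch_all = [], [], []
    t_cursor = 0.0

    for entry in schedule:
        activity, duration, extra = _parse_entry(entry)
        n = int(round(duration * fs))
        terrain = extra.pop("terrain", "lab" if activity == "walk" else "none")
        environment = extra.pop("environment", "indoor")
        task = extra.pop("task", "single")
        dyn = np.zeros((3, n))
        if activity == "walk":
            seg_params = replace(
                params,
                duration_s=duration,
                noise_sd=0.0,
                seed=int(rng.integers(2**31)),
                **extra,
            )
            rec_seg, truth_seg = simulate_walk(seg_params)
            dyn[2] = rec_seg.az - G
            ic_all.append(truth_seg.ic_times + t_cursor)
            fc_all.append(truth_seg.fc_times + t_cursor)
            side_all.append(truth_seg.sides)
            st_all.append(truth_seg.step_times)
            sl_all.append(truth_seg.step_lengths)
            ch_all.append(truth_seg.com_heights)
        elif extra:
            raise ParameterError(f"overrides not supported for activity {activity!r}: {extra}")
        base = np.tile(np.asarray(baselines[activity])[:, None], (1, n))
        seg_arrays.append(base + dyn)
        labels.append(
            ContextLabel(
                start=t_cursor,
                end=t_cursor + duration,
                terrain=terrain,
                environment=environment,
                task=task,
                notes=activity,
            )
        )
        t_cursor += duration

    signal = np.concatenate(seg_arrays, axis=1)

    # Cosine-taper the gravity reorientation across each segment boundary.
    n_tap = int(round(taper_s * fs))
    if n_tap > 1:
        edges = np.cumsum([int(round(_parse_entry(e)[1] * fs)) for e in schedule])[:-1]
        for k, edge in enumerate(edges):
            b0 = np.asarray(baselines[_parse_entry(schedule[k])[0]])
            b1 = np.asarray(baselines[_parse_entry(schedule[k + 1])[0]])
            if np.allclose(b0, b1):
                continue
            i0 = max(edge - n_tap // 2, 0)
            i1 = min(edge + n_tap // 2, signal.shape[1])
            w = 0.5 * (1 - np.cos(np.pi * np.arange(i1 - i0) / max(i1 - i0 - 1, 1)))
            old = signal[:, i0:i1] - np.where(
                np.arange(i0, i1) < edge, b0[:, None], b1[:, None]
            )
            signal[:, i0:i1] = old + np.outer(b0, 1 - w) + np.outer(b1, w)

    rec = AccelRecording(
        start_time=0.0, fs=fs, ax=signal[0], ay=signal[1], az=signal[2]
    )
    if params.noise_sd > 0:
        rec = add_sensor_noise(rec, params.noise_sd, seed=int(rng.integers(2**31)))

    def _cat(parts, dtype=float):
        return (
            np.concatenate(parts) if parts else np.array([], dtype=dtype)
        )

    truth = GroundTruth(
        ic_times=_cat(ic_all),
        fc_times=_cat(fc_all),
        sides=_cat(side_all, dtype=object),
        step_times=_cat(st_all),
        step_lengths=_cat(sl_all),
        com_heights=_cat(ch_all),
    )
    return rec, truth, labels
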
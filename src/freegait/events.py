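"""Gaussian-CWT initial/final contact detection on the vertical acceleration.

Chain: the gravity-removed vertical acceleration a_v (signed positive in the
direction of gravity) is integrated, detrended, and differentiated with a
Gaussian continuous wavelet (a first-derivative-of-Gaussian smoothing
differentiator) at a scale tuned to the dominant step frequency.  Initial
contacts are minima of that signal; final contacts are maxima of a further
CWT differentiation.  Minima/maxima are located coarse-to-fine: found at the
step-frequency scale, then refined on a half-scale version to remove the
baseline-induced position bias the heavier smoothing introduces.
"""
from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter1d
from scipy.signal import detrend, find_peaks, welch

from .config import PipelineConfig
from .types import (
    AccelRecording,
    CwtSignals,
    DataError,
    G,
    GaitEvents,
    OrientationError,
    VerticalSeries,
    WalkingBout,
    convert_units,
)

log = logging.getLogger("freegait")

#: Band searched for the dominant step frequency (Hz).
STEP_BAND = (0.5, 3.0)
#: Fallback step frequency when no spectral peak is found (Hz).
FALLBACK_F0 = 2.0


def vertical_component(
    rec: AccelRecording,
    bout: Optional[WalkingBout] = None,
    pad_s: float = 1.0,
) -> VerticalSeries:
    """Extract gravity-removed vertical acceleration over a bout.

    The vertical direction is the signed device axis whose mean over the
    bout is closest to +1 g; gravity is removed by subtracting the bout
    mean.  The returned series is padded by ``pad_s`` of neighbouring
    recording (when available) so events at the bout boundary remain
    detectable; the bout proper is recorded as ``core_start``/``core_end``.

    a_v is signed positive in the direction of gravity (downward), the
    convention under which heel strikes are minima of the smoothed signal.
    """
    rec = convert_units(rec, "m_per_s2")
    if bout is None:
        bout = WalkingBout(start=0.0, end=rec.duration_s)
    i0 = int(round(bout.start * rec.fs))
    i1 = int(round(bout.end * rec.fs))
    if i0 < 0 or i1 > rec.n_samples or i1 <= i0:
        raise DataError("bout must lie within the recording")
    p = int(round(pad_s * rec.fs))
    j0, j1 = max(i0 - p, 0), min(i1 + p, rec.n_samples)

    best_axis, best_sign, best_mean = None, 1.0, -np.inf
    for name in ("ax", "ay", "az"):
        m = float(np.mean(rec.axis(name)[i0:i1]))
        for sign in (1.0, -1.0):
            if sign * m > best_mean:
                best_axis, best_sign, best_mean = name, sign, sign * m
    if best_mean < np.cos(np.deg2rad(30.0)) * G:
        raise OrientationError(
            f"no axis within 30 degrees of gravity (best {best_axis} at "
            f"{best_mean / G:.2f} g); device likely worn incorrectly"
        )
    sig_up = best_sign * rec.axis(best_axis)[j0:j1]
    a_v = float(np.mean(sig_up)) - sig_up          # down-positive dynamic part
    t = np.arange(j0, j1) / rec.fs
    return VerticalSeries(t=t, a_v=a_v, core_start=bout.start, core_end=bout.end)


def _robust_amplitude(x: np.ndarray) -> float:
    """Amplitude of the dominant oscillation, insensitive to transients.

    sqrt(2) * 1.4826 * MAD equals the amplitude of a pure sinusoid and is
    unaffected by a minority of large bout-edge excursions.
    """
    return float(np.sqrt(2) * 1.4826 * np.median(np.abs(x - np.median(x))))


def _dominant_frequency(y: np.ndarray, fs: float) -> Optional[float]:
    nperseg = min(len(y), 1024)
    f, p = welch(y, fs=fs, nperseg=nperseg)
    band = (f >= STEP_BAND[0]) & (f <= STEP_BAND[1])
    if not band.any():
        return None
    pb = p[band]
    if pb.max() <= 0 or pb.max() < 1e-12 * p.max():
        return None
    return float(f[band][np.argmax(pb)])


def cwt_chain(
    v: VerticalSeries,
    scale_policy="auto",
) -> CwtSignals:
    """Integrate a_v and differentiate twice with a Gaussian CWT.

    ``y_int`` is the linearly-detrended cumulative trapezoidal integral;
    ``d1``/``d2`` are successive Gaussian-derivative differentiations at a
    scale whose centre frequency matches the dominant spectral peak of
    ``y_int`` in 0.5-3 Hz (policy ``"auto"``), or a fixed frequency in Hz.
    The operator is linear and phase-exact (zero-lag kernel).
    """
    fs = v.fs
    if len(v.t) < int(4 * fs):
        raise DataError("need at least 4 s of signal for the CWT chain")
    dt = 1.0 / fs
    y = cumulative_trapezoid(v.a_v, dx=dt, initial=0.0)
    y = detrend(y)
    if scale_policy == "auto":
        f0 = _dominant_frequency(y, fs)
        if f0 is None:
            log.warning("no spectral peak in %s-%s Hz; falling back to %s Hz",
                        *STEP_BAND, FALLBACK_F0)
            f0 = FALLBACK_F0
    else:
        f0 = float(scale_policy)
    sigma = fs / (2 * np.pi * f0)          # centre frequency of G' = 1/(2*pi*sigma_t)
    d1 = gaussian_filter1d(y, sigma, order=1, mode="nearest") * fs
    d2 = gaussian_filter1d(d1, sigma, order=1, mode="nearest") * fs
    return CwtSignals(
        t=v.t, y_int=y, d1=d1, d2=d2, scale=sigma, f0=f0, fs=fs,
        core_start=v.core_start, core_end=v.core_end,
    )


def _extrema_times(
    sig: CwtSignals,
    source: np.ndarray,
    mode: str,
    min_prominence_frac: float,
    min_separation_s: float,
    edge_exclude_s: float,
    fine: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Shared minima/maxima detector with optional coarse-to-fine refinement.

    Extrema are found at the step-frequency scale (robust to noise); when a
    less-smoothed ``fine`` signal is given, each extremum is relocated to
    the local maximum of ``fine`` (oriented upward) within 15% of the median
    inter-event interval, removing the position bias that heavier smoothing
    introduces next to asymmetric baselines.  Sub-sample positions come
    from a parabolic fit.
    """
    x = -source if mode == "min" else source
    prom = min_prominence_frac * _robust_amplitude(source)
    if prom <= 0:
        return np.array([])
    dist = max(int(round(min_separation_s * sig.fs)), 1)
    peaks, _ = find_peaks(x, prominence=prom, distance=dist)
    edge = int(round(edge_exclude_s * sig.fs))
    peaks = peaks[(peaks >= edge) & (peaks <= len(x) - 1 - edge)]
    if len(peaks) < 2:
        return np.array([])

    if fine is not None and len(peaks) >= 2:
        half = max(int(round(0.15 * float(np.median(np.diff(peaks))))), 2)
        refined = []
        for p in peaks:
            a, b = max(p - half, 0), min(p + half + 1, len(fine))
            refined.append(a + int(np.argmax(fine[a:b])))
        peaks = np.asarray(refined)
    else:
        fine = x

    times = []
    for p in peaks:
        if 0 < p < len(fine) - 1:
            y0, y1, y2 = fine[p - 1], fine[p], fine[p + 1]
            den = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / den if den < 0 else 0.0
        else:
            delta = 0.0
        times.append(sig.t[0] + (p + delta) / sig.fs)
    return np.asarray(times)


def _clip_to_core(times: np.ndarray, sig: CwtSignals) -> np.ndarray:
    if sig.core_start is None or len(times) == 0:
        return times
    return times[(times >= sig.core_start) & (times < sig.core_end)]


def detect_ic(sig: CwtSignals, cfg: Optional[PipelineConfig] = None) -> np.ndarray:
    """Initial contact times: minima of d1 inside the bout core."""
    cfg = cfg or PipelineConfig()
    fine = -gaussian_filter1d(sig.y_int, sig.scale / 2, order=1, mode="nearest") * sig.fs
    times = _extrema_times(
        sig, sig.d1, "min",
        cfg.min_prominence_frac, cfg.min_separation_s, cfg.edge_exclude_s,
        fine=fine,
    )
    return _clip_to_core(times, sig)


def detect_fc(sig: CwtSignals, cfg: Optional[PipelineConfig] = None) -> np.ndarray:
    """Final contact times: maxima of d2 inside the bout core."""
    cfg = cfg or PipelineConfig()
    times = _extrema_times(
        sig, sig.d2, "max",
        cfg.min_prominence_frac, cfg.min_separation_s, cfg.edge_exclude_s,
    )
    return _clip_to_core(times, sig)


def pair_events(
    ic: np.ndarray,
    fc: np.ndarray,
    cfg: Optional[PipelineConfig] = None,
    source_bout: Optional[str] = None,
) -> GaitEvents:
    """Match each IC to the first FC occurring 0.1-0.9 step times later.

    T is the median inter-IC interval.  The matched FC is physiologically
    the contralateral toe-off; the temporal stage re-indexes it to the
    correct side.  Sides alternate starting from ``cfg.first_side``.  More
    than 25% unmatched events flags the bout as low quality.
    """
    cfg = cfg or PipelineConfig()
    ic = np.sort(np.asarray(ic, dtype=float))
    fc = np.sort(np.asarray(fc, dtype=float))
    n = len(ic)
    matched = np.full(n, np.nan)
    used = np.zeros(len(fc), dtype=bool)
    if n >= 2:
        T = float(np.median(np.diff(ic)))
        for i, tic in enumerate(ic):
            lo, hi = tic + cfg.pair_lo_frac * T, tic + cfg.pair_hi_frac * T
            cand = np.flatnonzero((fc > lo) & (fc < hi) & ~used)
            if len(cand):
                matched[i] = fc[cand[0]]
                used[cand[0]] = True
    n_un_ic = int(np.sum(~np.isfinite(matched)))
    n_un_fc = int(np.sum(~used))
    total = n + len(fc)
    low_quality = total > 0 and (n_un_ic + n_un_fc) / total > 0.25
    if n_un_ic or n_un_fc:
        log.info("pair_events: %d ICs and %d FCs unmatched", n_un_ic, n_un_fc)
    sides = np.empty(n, dtype=object)
    order = ("L", "R") if cfg.first_side == "L" else ("R", "L")
    sides[0::2], sides[1::2] = order[0], order[1]
    return GaitEvents(
        ic_times=ic, fc_times=matched, sides=sides,
        source_bout=source_bout,
        n_unmatched_ic=n_un_ic, n_unmatched_fc=n_un_fc,
        low_quality=low_quality,
    )


def detect_events(
    rec: AccelRecording,
    bout: WalkingBout,
    cfg: Optional[PipelineConfig] = None,
    source_bout: Optional[str] = None,
) -> tuple[GaitEvents, VerticalSeries, CwtSignals]:
    """Full per-bout chain: vertical component -> CWT -> IC/FC -> pairing."""
    cfg = cfg or PipelineConfig()
    v = vertical_component(rec, bout, pad_s=cfg.bout_pad_s)
    sig = cwt_chain(v, cfg.scale_policy)
    ic = detect_ic(sig, cfg)
    fc = detect_fc(sig, cfg)
    ev = pair_events(ic, fc, cfg, source_bout=source_bout)
    return ev, v, sig


def bout_has_gait(
    rec: AccelRecording, bout: WalkingBout, cfg: Optional[PipelineConfig] = None
) -> bool:
    """Confirmation step: a bout is gait if >= 4 alternating ICs are found."""
    cfg = cfg or PipelineConfig()
    try:
        v = vertical_component(rec, bout, pad_s=cfg.bout_pad_s)
        sig = cwt_chain(v, cfg.scale_policy)
        ic = detect_ic(sig, cfg)
    except (DataError, OrientationError):
        return False
    return len(ic) >= 4
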
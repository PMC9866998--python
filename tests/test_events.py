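"""CWT chain correctness and IC/FC detection against analytic and simulated truth."""
import numpy as np
import pytest

from freegait import (
    PipelineConfig,
    SimParams,
    WalkingBout,
    cwt_chain,
    detect_events,
    detect_fc,
    detect_ic,
    pair_events,
    simulate_recording,
    vertical_component,
)
from freegait.events import _extrema_times
from freegait.types import DataError, G, OrientationError, VerticalSeries


def _sine_series(f=2.0, fs=100.0, duration=30.0, amp=1.0):
    t = np.arange(0, duration, 1 / fs)
    return VerticalSeries(t=t, a_v=amp * np.sin(2 * np.pi * f * t))


def _phase_deg(x, t, f):
    """Phase of x relative to sin(2*pi*f*t) by least squares."""
    a = np.vstack([np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)]).T
    cs, cc = np.linalg.lstsq(a, x, rcond=None)[0]
    return np.degrees(np.arctan2(cc, cs))


class TestVerticalComponent:
    def test_selects_simulator_vertical_axis(self, padded_walk):
        rec, _, _ = padded_walk
        v = vertical_component(rec, WalkingBout(5, 35))
        assert abs(v.a_v.mean()) < 1e-6          # gravity removed
        assert np.std(v.a_v) > 0.5               # gait dynamics present

    def test_rest_segment_is_near_zero(self):
        rec, _, _ = simulate_recording([("stand", 10)], SimParams(noise_sd=0))
        v = vertical_component(rec)
        np.testing.assert_allclose(v.a_v, 0.0, atol=1e-9)

    def test_rotation_invariance(self, padded_walk):
        """Permuting axes in software must not change a_v."""
        rec, _, _ = padded_walk
        rotated = type(rec)(
            start_time=rec.start_time, fs=rec.fs,
            ax=rec.az, ay=rec.ax, az=rec.ay, units=rec.units,
        )
        bout = WalkingBout(5, 35)
        v0 = vertical_component(rec, bout)
        v1 = vertical_component(rotated, bout)
        np.testing.assert_allclose(v1.a_v, v0.a_v, atol=1e-6)

    def test_no_gravity_axis_is_orientation_error(self):
        from freegait.types import AccelRecording

        n = 1000
        tilted = AccelRecording(
            0.0, 100.0,
            np.full(n, G / np.sqrt(3)), np.full(n, G / np.sqrt(3)), np.full(n, G / np.sqrt(3)),
        )
        with pytest.raises(OrientationError):
            vertical_component(tilted)


class TestCwtChain:
    def test_sinusoid_phases(self):
        """a_v = sin -> y_int ~ -cos, d1 ~ sin, d2 ~ cos within 5 degrees."""
        v = _sine_series()
        sig = cwt_chain(v, scale_policy="auto")
        assert sig.f0 == pytest.approx(2.0, abs=0.1)
        m = slice(200, 2800)  # trim edges
        assert abs(_phase_deg(sig.y_int[m], v.t[m], 2.0) - (-90)) < 5
        assert abs(_phase_deg(sig.d1[m], v.t[m], 2.0)) < 5
        assert abs(_phase_deg(sig.d2[m], v.t[m], 2.0) - 90) < 5

    def test_zero_signal_chain_is_zero(self):
        t = np.arange(0, 10, 0.01)
        sig = cwt_chain(VerticalSeries(t=t, a_v=np.zeros_like(t)))
        np.testing.assert_allclose(sig.d1, 0.0, atol=1e-12)
        np.testing.assert_allclose(sig.d2, 0.0, atol=1e-12)

    def test_linearity(self):
        v1 = _sine_series(amp=1.0)
        v2 = _sine_series(amp=2.0)
        s1 = cwt_chain(v1, scale_policy=2.0)
        s2 = cwt_chain(v2, scale_policy=2.0)
        np.testing.assert_allclose(s2.d1, 2 * s1.d1, atol=1e-9)
        np.testing.assert_allclose(s2.d2, 2 * s1.d2, atol=1e-9)

    def test_matches_pywt_gaussian_cwt(self):
        """Independent oracle: same operator as pywt's gaus1 CWT (up to sign)."""
        pywt = pytest.importorskip("pywt")
        v = _sine_series(f=1.9)
        sig = cwt_chain(v, scale_policy=1.9)
        fs = 100.0
        scale = pywt.central_frequency("gaus1") * fs / 1.9
        ref = -pywt.cwt(sig.y_int, [scale], "gaus1", sampling_period=1 / fs)[0][0]
        m = slice(300, 2700)
        r = np.corrcoef(sig.d1[m], ref[m])[0, 1]
        assert r > 0.99

    def test_too_short_signal_rejected(self):
        t = np.arange(0, 2, 0.01)
        with pytest.raises(DataError):
            cwt_chain(VerticalSeries(t=t, a_v=np.sin(t)))


class TestDetectIc:
    def test_sine_minima_spacing(self, cfg):
        sig = cwt_chain(_sine_series(f=2.0))
        ic = detect_ic(sig, cfg)
        assert len(ic) > 50
        np.testing.assert_allclose(np.diff(ic), 0.5, atol=0.011)

    def test_zero_signal_empty(self, cfg):
        t = np.arange(0, 10, 0.01)
        sig = cwt_chain(VerticalSeries(t=t, a_v=np.zeros_like(t)))
        assert len(detect_ic(sig, cfg)) == 0

    def test_simulator_count_within_one_of_truth(self, cfg, padded_walk):
        rec, truth, _ = padded_walk
        ev, _, _ = detect_events(rec, WalkingBout(5, 35), cfg)
        assert abs(ev.n_ic - len(truth.ic_times)) <= 1

    def test_parameter_recovery_with_noise(self, cfg):
        """Detected ICs track truth within 0.05 s under moderate noise."""
        matched = total = 0
        dt_err = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            T = rng.uniform(0.45, 0.65)
            p = SimParams(
                step_time_mean_l=T, step_time_mean_r=T, step_time_sd=0.0,
                noise_sd=0.4, seed=seed,
            )
            rec, truth, _ = simulate_recording([("stand", 4), ("walk", 30), ("stand", 4)], p)
            ev, _, _ = detect_events(rec, WalkingBout(4, 34), cfg)
            total += len(truth.ic_times)
            for x in truth.ic_times:
                if ev.n_ic and np.min(np.abs(ev.ic_times - x)) <= 0.05:
                    matched += 1
            dt_err.append(abs(np.mean(np.diff(ev.ic_times)) - T))
        assert matched / total >= 0.95
        assert np.mean(dt_err) < 0.01

    def test_shift_equivariance(self, cfg):
        """Translating the series shifts every event time by the same amount."""
        v = _sine_series()
        shift = 17 / 100.0
        v2 = VerticalSeries(t=v.t + shift, a_v=v.a_v)
        ic1 = detect_ic(cwt_chain(v), cfg)
        ic2 = detect_ic(cwt_chain(v2), cfg)
        np.testing.assert_allclose(ic2, ic1 + shift, atol=1e-9)

    def test_sign_symmetry_with_fc_detector(self, cfg):
        """Minima of d1 equal maxima of -d1 found by the same machinery."""
        sig = cwt_chain(_sine_series())
        minima = _extrema_times(
            sig, sig.d1, "min", cfg.min_prominence_frac,
            cfg.min_separation_s, cfg.edge_exclude_s,
        )
        maxima_of_neg = _extrema_times(
            sig, -sig.d1, "max", cfg.min_prominence_frac,
            cfg.min_separation_s, cfg.edge_exclude_s,
        )
        np.testing.assert_allclose(minima, maxima_of_neg, atol=1e-12)


class TestDetectFc:
    def test_sine_maxima_spacing(self, cfg):
        sig = cwt_chain(_sine_series(f=2.0))
        fc = detect_fc(sig, cfg)
        assert len(fc) > 50
        np.testing.assert_allclose(np.diff(fc), 0.5, atol=0.011)

    def test_one_fc_between_consecutive_ics(self, cfg, padded_walk):
        rec, _, _ = padded_walk
        ev, _, _ = detect_events(rec, WalkingBout(5, 35), cfg)
        matched = np.isfinite(ev.fc_times)
        assert matched[1:].mean() > 0.9          # first IC has no preceding FC


class TestPairEvents:
    def test_worked_matching_example(self, cfg):
        """T=0.5; FC window is (0.05, 0.45) after each IC."""
        ev = pair_events(np.array([1.0, 1.5, 2.0]), np.array([1.65, 2.15]), cfg)
        assert np.isnan(ev.fc_times[0])
        assert ev.fc_times[1] == pytest.approx(1.65)
        assert ev.fc_times[2] == pytest.approx(2.15)
        assert ev.n_unmatched_ic == 1

    def test_empty_fc_leaves_all_unpaired(self, cfg):
        ev = pair_events(np.array([1.0, 1.5, 2.0]), np.array([]), cfg)
        assert np.all(np.isnan(ev.fc_times))
        assert ev.low_quality          # 3 of 3 events unmatched

    def test_truth_events_pair_without_drops(self, cfg, level_walk):
        _, truth = level_walk
        ev = pair_events(truth.ic_times, truth.fc_times, cfg)
        assert ev.n_unmatched_fc == 0
        # only the boundary ICs (no preceding/following toe-off) lack a match
        assert np.isfinite(ev.fc_times[1:-1]).all()
        assert list(ev.sides[:4]) == ["L", "R", "L", "R"]
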
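"""Temporal/spatial per-step characteristics against hand-traced and analytic oracles."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from freegait import (
    GaitEvents,
    SimParams,
    WalkingBout,
    com_vertical_displacement,
    compute_step_table,
    detect_events,
    simulate_recording,
    step_lengths,
    step_velocities,
    temporal_characteristics,
    vertical_component,
)
from freegait.types import ComTrace, DataError, VerticalSeries


def _events(ic, fc=None, first="L"):
    ic = np.asarray(ic, dtype=float)
    fc = np.full(len(ic), np.nan) if fc is None else np.asarray(fc, dtype=float)
    sides = np.array([("L", "R")[(i + (first == "R")) % 2] for i in range(len(ic))], dtype=object)
    return GaitEvents(ic_times=ic, fc_times=fc, sides=sides)


class TestTemporalCharacteristics:
    def test_hand_traced_stance_and_swing(self):
        """ICs [0, .5, 1]; same-side toe-offs at 0.65 and 1.15.

        The FC at 0.65 is detected after the IC at 0.5, so it is stored
        aligned to that IC; it is the toe-off of the foot that struck at 0.
        """
        ev = _events([0.0, 0.5, 1.0], [np.nan, 0.65, 1.15])
        tbl = temporal_characteristics(ev)
        np.testing.assert_allclose(tbl["step_time"], [0.5, 0.5])
        np.testing.assert_allclose(tbl["stance_time"], [0.65, 0.65])
        assert tbl["swing_time"][0] == pytest.approx(0.35)
        assert np.isnan(tbl["swing_time"][1])    # needs the IC after next

    def test_single_ic_gives_empty_table(self):
        tbl = temporal_characteristics(_events([1.0]))
        assert len(tbl) == 0

    def test_truth_events_reproduce_step_time(self, level_walk):
        _, truth = level_walk
        ev = _events(truth.ic_times)
        tbl = temporal_characteristics(ev)
        np.testing.assert_allclose(tbl["step_time"], 0.524, atol=1e-9)

    def test_non_alternating_sides_rejected(self):
        ev = _events([0.0, 0.5, 1.0])
        ev.sides[1] = "L"
        with pytest.raises(DataError, match="alternate"):
            temporal_characteristics(ev)

    def test_stance_plus_swing_equals_stride(self, cfg, padded_walk):
        """Same-side stance + swing must equal the same-side stride exactly."""
        rec, _, _ = padded_walk
        ev, v, _ = detect_events(rec, WalkingBout(5, 35), cfg)
        tbl = temporal_characteristics(ev)
        ic = ev.ic_times
        for i in range(len(tbl) - 2):
            stance, swing = tbl["stance_time"][i], tbl["swing_time"][i]
            if np.isfinite(stance) and np.isfinite(swing):
                stride = ic[i + 2] - ic[i]
                assert stance + swing == pytest.approx(stride, abs=1e-12)


class TestComVerticalDisplacement:
    def test_sinusoid_closed_form(self):
        """a_v = A sin(2*pi*f*t), one-period steps: h = 2A/(2*pi*f)^2."""
        f, amp = 2.0, 1.0
        t = np.arange(0, 30, 0.01)
        v = VerticalSeries(t=t, a_v=amp * np.sin(2 * np.pi * f * t))
        ic = np.arange(0.0, 29.5, 1 / f)
        trace = com_vertical_displacement(v, _events(ic))
        expected = 2 * amp / (2 * np.pi * f) ** 2
        settled = trace.h[10:-10]
        np.testing.assert_allclose(settled, expected, rtol=0.01)
        assert expected == pytest.approx(0.012665, abs=1e-6)

    def test_zero_acceleration_gives_zero_height(self):
        t = np.arange(0, 10, 0.01)
        v = VerticalSeries(t=t, a_v=np.zeros_like(t))
        trace = com_vertical_displacement(v, _events([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(trace.h, 0.0, atol=1e-12)

    def test_short_step_undefined(self):
        t = np.arange(0, 10, 0.01)
        v = VerticalSeries(t=t, a_v=np.sin(t))
        trace = com_vertical_displacement(v, _events([1.0, 1.02, 3.0]))
        assert np.isnan(trace.h[0])
        assert np.isfinite(trace.h[1])

    def test_recovers_constructed_excursion(self, cfg):
        """Noise-free simulator: per-step h within 1% of the built trajectory."""
        p = SimParams(duration_s=40, step_time_sd=0, noise_sd=0, seed=1)
        from freegait import simulate_walk

        rec, truth = simulate_walk(p)
        v = vertical_component(rec, WalkingBout(0, 40), pad_s=0)
        trace = com_vertical_displacement(v, _events(truth.ic_times))
        settle = 2.0 / cfg.highpass_hz
        ok = (truth.ic_times[:-1] >= settle) & (truth.ic_times[1:] <= 40 - settle)
        rel = np.abs(trace.h[ok] - truth.com_heights[ok]) / truth.com_heights[ok]
        assert rel.max() < 0.01


class TestStepLengths:
    def test_zero_height_zero_length(self):
        trace = ComTrace(h=np.array([0.0]), displacement=np.zeros(2), t=np.arange(2.0))
        assert step_lengths(trace, 0.9)[0] == 0.0

    def test_direct_formula_value(self):
        trace = ComTrace(h=np.array([0.05]), displacement=np.zeros(2), t=np.arange(2.0))
        assert step_lengths(trace, 0.9)[0] == pytest.approx(2 * np.sqrt(0.0875), abs=1e-6)
        assert step_lengths(trace, 0.9)[0] == pytest.approx(0.5916, abs=1e-4)

    def test_geometry_violation_marked_nan(self):
        trace = ComTrace(h=np.array([0.95, 0.05]), displacement=np.zeros(2), t=np.arange(2.0))
        out = step_lengths(trace, 0.9)
        assert np.isnan(out[0]) and np.isfinite(out[1])

    def test_simulator_inverse_recovery(self, cfg):
        """Noise-free full pipeline: step length within 5% of the true chord."""
        p = SimParams(duration_s=40, step_time_sd=0, noise_sd=0, seed=2)
        rec, truth, _ = simulate_recording([("stand", 6), ("walk", 40), ("stand", 6)], p)
        ev, v, _ = detect_events(rec, WalkingBout(6, 46), cfg)
        tbl = compute_step_table(v, ev, cfg)
        lengths = tbl["step_length"].to_numpy()
        settle = 2.0 / cfg.highpass_hz
        inner = lengths[(tbl["ic_time"] > 6 + settle) & (tbl["ic_time"] < 46 - settle - 0.6)]
        rel = np.abs(inner - 0.562) / 0.562
        assert np.nanmax(rel) < 0.05


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 0.89), min_size=2, max_size=10))
def test_step_length_monotone_in_height(hs):
    """The pendulum formula is increasing in h on [0, l)."""
    hs = np.sort(np.asarray(hs))
    trace = ComTrace(h=hs, displacement=np.zeros(2), t=np.arange(2.0))
    out = step_lengths(trace, 0.9)
    assert np.all(np.diff(out) >= -1e-12)


class TestStepVelocities:
    def test_division_and_propagation(self):
        tbl = pd.DataFrame(
            {"step_time": [0.524, 0.5, 0.5], "step_length": [0.5916, 0.0, np.nan]}
        )
        out = step_velocities(tbl)
        assert out["step_velocity"][0] == pytest.approx(1.129, abs=1e-3)
        assert out["step_velocity"][1] == 0.0
        assert np.isnan(out["step_velocity"][2])

    def test_doubling_times_halves_velocities(self):
        tbl = pd.DataFrame({"step_time": [0.4, 0.6], "step_length": [0.5, 0.7]})
        v1 = step_velocities(tbl)["step_velocity"]
        tbl2 = tbl.assign(step_time=tbl["step_time"] * 2)
        v2 = step_velocities(tbl2)["step_velocity"]
        np.testing.assert_allclose(v2, v1 / 2)
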
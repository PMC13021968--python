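"""ΔF/F computation, shock schedules, and second-half AUC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from danscreen.errors import DegenerateReferenceError, InsufficientDataError, ProtocolError
from danscreen.imaging import (
    DFFTrace,
    ShockProtocol,
    ShockTrace,
    compare_shock_responses,
    compute_dff,
    second_half_auc,
    shock_onsets,
)
from danscreen.synthetic import StudyConfig, gen_traces, pulse_waveform

N_FRAMES = 600  # 4 Hz x 150 s


def flat_trace(value=100.0):
    return ShockTrace((value,) * N_FRAMES)


class TestProtocol:
    def test_default_onsets_are_45_to_100(self):
        onsets = shock_onsets(ShockProtocol())
        assert onsets == [45.0 + 5.0 * k for k in range(12)]
        assert len(onsets) == 12

    def test_single_pulse(self):
        assert shock_onsets(ShockProtocol(n_pulses=1)) == [45.0]

    def test_pulse_longer_than_interval_rejected(self):
        with pytest.raises(ProtocolError):
            ShockProtocol(pulse_duration=6.0, inter_onset_interval=5.0)

    def test_schedule_exceeding_recording_rejected(self):
        with pytest.raises(ProtocolError):
            shock_onsets(ShockProtocol(n_pulses=30))

    def test_trace_length_must_match_rate_and_duration(self):
        with pytest.raises(ProtocolError):
            ShockTrace((100.0,) * 10)


class TestComputeDff:
    def test_constant_trace_is_all_zero(self):
        dff = compute_dff(flat_trace(), ShockProtocol())
        assert np.allclose(dff.values, 0.0)

    def test_plateau_after_onset_is_50_percent(self):
        t = np.arange(N_FRAMES) / 4.0
        f = np.where(t >= 45.0, 150.0, 100.0)
        dff = compute_dff(ShockTrace(tuple(f)), ShockProtocol())
        assert np.allclose(np.asarray(dff.values)[t >= 45.0], 50.0)
        assert np.allclose(np.asarray(dff.values)[t < 45.0], 0.0)

    def test_baseline_window_mean_is_zero(self):
        rng = np.random.default_rng(0)
        f = 100.0 + rng.uniform(-5, 5, N_FRAMES)
        dff = compute_dff(ShockTrace(tuple(f)), ShockProtocol())
        t = dff.times
        lo, hi = dff.baseline_window
        window = np.asarray(dff.values)[(t >= lo) & (t < hi)]
        assert window.mean() == pytest.approx(0.0, abs=1e-9)

    def test_zero_baseline_is_degenerate(self):
        t = np.arange(N_FRAMES) / 4.0
        f = np.where(t >= 44.0, 100.0, 0.0)  # F0 window mostly zero
        with pytest.raises(DegenerateReferenceError):
            compute_dff(ShockTrace(tuple(np.where(t < 45.0, 0.0, f))), ShockProtocol())

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_gain_invariance(self, gain):
        rng = np.random.default_rng(1)
        f = 100.0 + rng.uniform(-5, 5, N_FRAMES)
        base = compute_dff(ShockTrace(tuple(f)), ShockProtocol())
        scaled = compute_dff(ShockTrace(tuple(f * gain)), ShockProtocol())
        assert np.allclose(base.values, scaled.values)


class TestSecondHalfAuc:
    def test_zero_trace_has_zero_auc(self):
        dff = compute_dff(flat_trace(), ShockProtocol())
        assert second_half_auc(dff, ShockProtocol()) == pytest.approx(0.0)

    def test_constant_10_percent_over_30s_window_is_300(self):
        dff = DFFTrace((10.0,) * N_FRAMES, 4.0, (40.0, 45.0))
        assert second_half_auc(dff, ShockProtocol()) == pytest.approx(300.0)

    def test_triangular_pulses_match_closed_form(self):
        cfg = StudyConfig(seed=0, trace_noise_sd=0.0)
        protocol = ShockProtocol()
        trace = gen_traces(cfg, "kd_like", protocol)[0]
        dff = compute_dff(trace, protocol)
        auc = second_half_auc(dff, protocol)
        # six pulses in the window, each a triangle of height amp and base
        # (rise + fall); breakpoints fall on the 4 Hz grid so the trapezoid
        # rule is exact
        expected = 6 * 0.5 * cfg.trace_amp_pct * (cfg.trace_rise_s + cfg.trace_fall_s)
        assert auc == pytest.approx(expected, rel=1e-9)

    def test_decaying_pulses_match_closed_form(self):
        cfg = StudyConfig(seed=0, trace_noise_sd=0.0)
        protocol = ShockProtocol()
        trace = gen_traces(cfg, "control_like", protocol)[0]
        auc = second_half_auc(compute_dff(trace, protocol), protocol)
        area = 0.5 * (cfg.trace_rise_s + cfg.trace_fall_s)
        expected = sum(
            cfg.trace_amp_pct * cfg.trace_decay**k * area for k in range(6, 12)
        )
        assert auc == pytest.approx(expected, rel=1e-9)

    @given(st.floats(-3.0, 3.0))
    @settings(max_examples=30, deadline=None)
    def test_linearity_in_dff(self, c):
        rng = np.random.default_rng(2)
        vals = rng.uniform(-5, 20, N_FRAMES)
        dff = DFFTrace(tuple(vals), 4.0, (40.0, 45.0))
        scaled = DFFTrace(tuple(c * vals), 4.0, (40.0, 45.0))
        protocol = ShockProtocol()
        assert second_half_auc(scaled, protocol) == pytest.approx(
            c * second_half_auc(dff, protocol), abs=1e-8
        )

    def test_window_captures_everything_when_signal_confined_to_it(self):
        t = np.arange(N_FRAMES) / 4.0
        vals = np.where((t >= 80.0) & (t <= 100.0), 7.0, 0.0)
        dff = DFFTrace(tuple(vals), 4.0, (40.0, 45.0))
        full = np.trapezoid(vals, t)
        assert second_half_auc(dff, ShockProtocol()) == pytest.approx(full)


class TestCompareShockResponses:
    def test_identical_groups_not_significant(self):
        g = [300.0, 310.0, 290.0, 305.0]
        res = compare_shock_responses(g, g)
        assert res.p_value > 0.9

    def test_sustained_vs_depressing_detected(self):
        cfg = StudyConfig(seed=42)
        protocol = ShockProtocol()
        ctrl = gen_traces(cfg, "control_like", protocol)
        kd = gen_traces(StudyConfig(seed=43), "kd_like", protocol)
        auc_c = [second_half_auc(compute_dff(t, protocol), protocol) for t in ctrl]
        auc_k = [second_half_auc(compute_dff(t, protocol), protocol) for t in kd]
        res = compare_shock_responses(auc_c, auc_k)
        assert np.mean(auc_k) > np.mean(auc_c)
        assert res.p_value < 0.05
        assert res.test_used == "mann_whitney"

    def test_single_element_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_shock_responses([1.0], [2.0])


def test_pulse_waveform_peak_and_support():
    t = np.arange(0, 20, 0.25)
    w = pulse_waveform(t, 5.0, 40.0, 1.25, 2.0)
    assert w.max() == pytest.approx(40.0)
    assert np.all(w[t < 5.0] == 0.0)
    assert np.all(w[t > 5.0 + 1.25 + 2.0] == 0.0)
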
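"""Normalization, cycle metrics, fatigue comparison, group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larvatrack import (
    StimulusProtocol,
    cycle_metrics,
    epoch_extract,
    fatigue_comparison,
    group_average_trace,
    normalize_trace,
    synthesize_perimeter_trace,
    two_group_test,
)
from larvatrack.metrics import NormalizedTrace
from larvatrack.stimulus import build_cycle_grid

PROTO = StimulusProtocol(delay_s=10, on_s=2, off_s=1, total_s=40)
GRID = build_cycle_grid(PROTO)


def make_norm(perimeter_norm, fps=10.0, proto=PROTO):
    n = len(perimeter_norm)
    times = np.arange(n) / fps
    return NormalizedTrace(
        time_s=times,
        perimeter_norm=np.asarray(perimeter_norm, float),
        led_on=proto.led_state(times),
        baseline_value=1.0,
        baseline_window=(proto.delay_s - 2, proto.delay_s),
        fps=fps,
    )


def square_wave(proto=PROTO, fps=10.0, lo=0.8):
    n = int(proto.total_s * fps)
    times = np.arange(n) / fps
    return np.where(proto.led_state(times), lo, 1.0)


class TestNormalizeTrace:
    def test_constant_perimeter_normalizes_to_one(self):
        track, stim = synthesize_perimeter_trace(PROTO, amplitudes=0.0)
        norm = normalize_trace(track, stim, fps=10)
        np.testing.assert_allclose(norm.perimeter_norm, 1.0)
        assert norm.baseline_value == pytest.approx(300.0)
        assert norm.baseline_window == (8.0, 10.0)

    def test_baseline_window_mean_is_one(self):
        track, stim = synthesize_perimeter_trace(
            PROTO, amplitudes=0.2, noise_sd=2.0, seed=4
        )
        norm = normalize_trace(track, stim, fps=10)
        t0, t1 = norm.baseline_window
        sel = (norm.time_s >= t0) & (norm.time_s < t1 - 1e-9)
        assert norm.perimeter_norm[sel].mean() == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        track, stim = synthesize_perimeter_trace(PROTO, amplitudes=0.2, seed=1)
        scaled = track.copy()
        scaled["perimeter"] = scaled["perimeter"] * scale
        n1 = normalize_trace(track, stim, fps=10)
        n2 = normalize_trace(scaled, stim, fps=10)
        np.testing.assert_allclose(n1.perimeter_norm, n2.perimeter_norm, rtol=1e-9)
        cy1 = cycle_metrics(n1, GRID)
        cy2 = cycle_metrics(n2, GRID)
        np.testing.assert_allclose(
            cy1["amplitude"].to_numpy(), cy2["amplitude"].to_numpy(), rtol=1e-9
        )

    def test_different_sizes_same_fraction_identical(self):
        t1, stim = synthesize_perimeter_trace(PROTO, rest_perimeter=300, amplitudes=0.15)
        t2, _ = synthesize_perimeter_trace(PROTO, rest_perimeter=450, amplitudes=0.15)
        n1 = normalize_trace(t1, stim, fps=10)
        n2 = normalize_trace(t2, stim, fps=10)
        np.testing.assert_allclose(n1.perimeter_norm, n2.perimeter_norm, rtol=1e-12)

    def test_missing_baseline_is_error(self):
        track, stim = synthesize_perimeter_trace(PROTO)
        track.loc[track["time_s"] < 10.0, "perimeter"] = np.nan
        with pytest.raises(ValueError, match="baseline"):
            normalize_trace(track, stim, fps=10)


class TestCycleMetrics:
    def test_flat_trace_zero_amplitude(self):
        cyc = cycle_metrics(make_norm(np.ones(400)), GRID)
        assert len(cyc) == 10
        np.testing.assert_allclose(cyc["amplitude"], 0.0)
        assert not cyc["flagged"].any()

    def test_square_wave_amplitude(self):
        cyc = cycle_metrics(make_norm(square_wave(lo=0.8)), GRID)
        np.testing.assert_allclose(cyc["rest_value"], 1.0)
        np.testing.assert_allclose(cyc["max_contraction_value"], 0.8)
        np.testing.assert_allclose(cyc["amplitude"], 0.2)

    def test_first_cycle_rest_is_baseline(self):
        cyc = cycle_metrics(make_norm(square_wave()), GRID)
        assert cyc.loc[0, "rest_value"] == 1.0

    def test_slow_response_reduces_amplitude_monotonically(self):
        amps = []
        for tau in (0.1, 0.5, 1.5):
            track, stim = synthesize_perimeter_trace(
                PROTO, amplitudes=0.2, response_tau=tau
            )
            norm = normalize_trace(track, stim, fps=10)
            cyc = cycle_metrics(norm, GRID)
            amps.append(cyc["amplitude"].mean())
        assert amps[0] > amps[1] > amps[2]
        assert amps[0] <= 0.2 + 1e-9

    def test_gap_interpolation_and_flagging(self):
        wave = square_wave()
        # short gap (2 frames) inside cycle 1's on-window: interpolated
        wave_short = wave.copy()
        wave_short[105:107] = np.nan
        cyc = cycle_metrics(make_norm(wave_short), GRID, max_gap_frames=3)
        assert not cyc.loc[0, "flagged"]
        assert cyc.loc[0, "amplitude"] == pytest.approx(0.2)
        # entire on-window missing: flagged, amplitude NaN, cycle kept
        wave_gone = wave.copy()
        wave_gone[100:120] = np.nan
        cyc2 = cycle_metrics(make_norm(wave_gone), GRID, max_gap_frames=3)
        assert cyc2.loc[0, "flagged"]
        assert np.isnan(cyc2.loc[0, "amplitude"])
        assert len(cyc2) == len(cyc)


class TestEpochExtract:
    def test_twenty_minute_protocol_yields_ten_epochs(self):
        proto = StimulusProtocol(10, 2, 1, 1210)
        n = int(1210 * 10)
        norm = make_norm(np.ones(n), proto=proto)
        epochs = epoch_extract(norm, epoch_len_s=20, every_s=120)
        assert len(epochs) == 10
        assert epochs[0].is_first and epochs[-1].is_last
        assert epochs[0].start_s == pytest.approx(10.0)
        assert epochs[-1].start_s == pytest.approx(10.0 + 9 * 120)
        assert all(len(e.time_s) == 200 for e in epochs)
        assert not any(e.truncated for e in epochs)

    def test_epoch_longer_than_trace_is_error(self):
        norm = make_norm(np.ones(100))
        with pytest.raises(ValueError):
            epoch_extract(norm, epoch_len_s=60, every_s=120)

    def test_stride_equal_to_trace_gives_single_epoch(self):
        norm = make_norm(np.ones(400))  # 40 s
        epochs = epoch_extract(norm, epoch_len_s=20, every_s=40)
        assert len(epochs) == 1
        assert epochs[0].is_first and epochs[0].is_last


class TestFatigueComparison:
    def test_constant_amplitudes(self):
        cyc = pd.DataFrame({"amplitude": [0.2] * 10})
        f = fatigue_comparison(cyc, k=3)
        assert f.difference == pytest.approx(0.0)
        assert f.ratio == pytest.approx(1.0)

    def test_linear_decay_closed_form(self):
        # amplitudes linearly decaying 0.2 -> 0.1 over 400 cycles
        n = 400
        amps = 0.2 - 0.1 * np.arange(n) / (n - 1)
        f = fatigue_comparison(pd.DataFrame({"amplitude": amps}), k=3)
        assert f.first_k_amplitude == pytest.approx(amps[:3].mean())
        assert f.last_k_amplitude == pytest.approx(amps[-3:].mean())
        assert f.first_k_amplitude == pytest.approx(0.2, abs=0.001)
        assert f.last_k_amplitude == pytest.approx(0.1, abs=0.001)

    def test_too_few_cycles_is_error(self):
        with pytest.raises(ValueError):
            fatigue_comparison(pd.DataFrame({"amplitude": [0.1] * 5}), k=3)


class TestGroupAverage:
    def test_identical_traces(self):
        n1 = make_norm(square_wave())
        n2 = make_norm(square_wave())
        g = group_average_trace([n1, n2])
        np.testing.assert_allclose(g["mean"], n1.perimeter_norm)
        np.testing.assert_allclose(g["sd"], 0.0)
        assert (g["n"] == 2).all()

    def test_hand_computed_sd(self):
        a = make_norm(np.full(300, 0.9))
        b = make_norm(np.full(300, 1.1))
        g = group_average_trace([a, b])
        np.testing.assert_allclose(g["mean"], 1.0)
        np.testing.assert_allclose(g["sd"], 0.14142135623730953, rtol=1e-12)

    def test_missing_frame_drops_pointwise_n(self):
        vals = np.ones(300)
        vals[50] = np.nan
        g = group_average_trace([make_norm(vals), make_norm(np.ones(300))])
        assert g.loc[50, "n"] == 1
        assert g.loc[49, "n"] == 2
        assert g.loc[50, "mean"] == 1.0

    def test_single_trace_warns_and_omits_sd(self, caplog):
        with caplog.at_level("WARNING"):
            g = group_average_trace([make_norm(np.ones(100))])
        assert g["sd"].isna().all()

    def test_permutation_invariance(self):
        traces = [make_norm(square_wave(lo=0.7 + 0.05 * i)) for i in range(4)]
        g1 = group_average_trace(traces)
        g2 = group_average_trace(traces[::-1])
        np.testing.assert_allclose(g1["mean"], g2["mean"])
        np.testing.assert_allclose(g1["sd"], g2["sd"])


class TestTwoGroupTest:
    def test_identical_groups_null(self):
        r = two_group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_pooled_t(self):
        # a = {1,2,3}, b = {11,12,13}: pooled s^2 = 1,
        # t = (2-12)/sqrt(1*(1/3+1/3)) = -12.2474
        r = two_group_test([1, 2, 3], [11, 12, 13])
        assert r.t_statistic == pytest.approx(-10 / np.sqrt(2 / 3), rel=1e-9)
        assert 0 < r.p_value < 0.001

    def test_zero_variance_shift_no_numerical_failure(self):
        r = two_group_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert 0 < r.p_value <= 1.0
        assert r.p_value < 1e-6

    def test_box_summary_quantities(self):
        a = np.arange(1, 12, dtype=float)  # 1..11
        r = two_group_test(a, a + 100)
        s = r.summary_a
        assert s.median == 6.0
        assert s.mean == 6.0
        assert s.q25 == pytest.approx(np.percentile(a, 25))
        assert s.whisker_hi == pytest.approx(np.percentile(a, 90))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_group_test([1.0], [1.0, 2.0])
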
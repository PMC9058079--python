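"""Gait-event detection: filter characteristics, peak/valley/crossing
rules against brute-force oracles, and segment separation."""

import numpy as np
import pytest

from tiltwalk import events as ev
from tiltwalk import synthgait as sg

from conftest import FS, foot_events, noise_free_config


def gaussian_bump(n, center, width, amp=100.0):
    i = np.arange(n)
    return amp * np.exp(-0.5 * ((i - center) / width) ** 2)


class TestLowpass:
    def test_dc_gain_unity(self):
        x = np.full(500, 7.0)
        np.testing.assert_allclose(ev.lowpass(x, FS), 7.0, atol=1e-9)

    def test_passband_amplitude_preserved(self):
        t = np.arange(0, 10, 1 / FS)
        y = ev.lowpass(np.sin(2 * np.pi * 1.0 * t), FS)
        measured = np.max(np.abs(y[200:-200]))
        predicted = 10 ** (ev.lowpass_response_db(1.0, FS) / 20)
        assert measured == pytest.approx(predicted, rel=1e-3)
        assert abs(measured - 1.0) < 0.01

    def test_stopband_attenuation(self):
        t = np.arange(0, 10, 1 / FS)
        y = ev.lowpass(np.sin(2 * np.pi * 25.0 * t), FS)
        measured_db = 20 * np.log10(np.max(np.abs(y[200:-200])))
        predicted_db = ev.lowpass_response_db(25.0, FS)
        assert measured_db == pytest.approx(predicted_db, abs=0.5)
        assert measured_db < -20.0

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            ev.lowpass(np.zeros(10), FS)

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            ev.lowpass(np.zeros(100), 20.0)

    def test_idempotent_in_passband(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.sin(2 * np.pi * 2.0 * t) + 0.5 * np.sin(2 * np.pi * 5.0 * t)
        once = ev.lowpass(x, FS)
        twice = ev.lowpass(once, FS)
        rms = np.sqrt(np.mean((twice - once) ** 2)) / np.sqrt(np.mean(once ** 2))
        assert rms < 0.01


class TestDetectMidswing:
    def test_flat_signal_empty(self):
        assert ev.detect_midswing(np.zeros(1000), FS).size == 0

    def test_three_bumps_found_at_centres(self):
        x = sum(gaussian_bump(500, c, 5.0) for c in (100, 200, 300))
        found = ev.detect_midswing(x, FS)
        # oracle: per-window argmax around each bump
        oracle = [c - 50 + np.argmax(x[c - 50:c + 50]) for c in (100, 200, 300)]
        np.testing.assert_array_equal(found, oracle)
        np.testing.assert_array_equal(found, [100, 200, 300])

    def test_min_separation_keeps_larger_peak(self):
        x = gaussian_bump(500, 200, 4.0, amp=80.0) + gaussian_bump(500, 230, 4.0, amp=100.0)
        found = ev.detect_midswing(x, FS, min_separation_s=0.4)
        # brute-force oracle: among peaks closer than the separation,
        # only the largest is admissible
        assert found.tolist() == [230]

    def test_adaptive_threshold_ignores_small_ripple(self):
        x = gaussian_bump(1000, 300, 5.0, amp=100.0) \
            + gaussian_bump(1000, 700, 5.0, amp=100.0)
        x += 2.0 * np.abs(np.sin(np.arange(1000) / 7.0))
        found = ev.detect_midswing(x, FS)
        assert sorted(found.tolist()) == [300, 700]


class TestDetectToeoff:
    def test_valley_before_peak_found(self):
        x = np.zeros(300)
        x[60:100] = -50.0 * np.sin(np.pi * np.arange(40) / 40)   # valley at 80
        x[100:140] = 100.0 * np.sin(np.pi * np.arange(40) / 40)
        ms = np.array([120])
        to = ev.detect_toeoff(x, ms, FS)
        assert to.tolist() == [60 + int(np.argmin(x[60:120]))] == [80]

    def test_monotonic_window_returns_start(self):
        x = np.arange(300.0)
        to = ev.detect_toeoff(x, np.array([200]), FS)
        assert to.tolist() == [200 - int(0.8 * FS)]

    def test_midswing_at_start_dropped(self):
        x = np.zeros(100)
        to = ev.detect_toeoff(x, np.array([0]), FS)
        assert to.tolist() == [-1]


class TestDetectHeelstrike:
    def test_sine_crest_to_downward_crossing(self):
        t = np.arange(0, 3, 1 / FS)
        x = np.sin(2 * np.pi * 1.0 * t)
        hs = ev.detect_heelstrike(x, np.array([25]))   # crest of cycle 1
        assert hs.tolist() == [50]   # analytic zero at t = 0.5 s

    def test_positive_tail_dropped(self):
        x = np.concatenate([np.sin(np.linspace(0, np.pi / 2, 50)), np.ones(100)])
        hs = ev.detect_heelstrike(x, np.array([49]))
        assert hs.tolist() == [-1]

    def test_synthetic_trial_heelstrikes_match_truth(self, trial_led_nf):
        for foot, trace in (("left", trial_led_nf.ankle_left),
                            ("right", trial_led_nf.ankle_right)):
            ge = foot_events(trace, foot)
            truth = trial_led_nf.truth.event_times[foot]["heelstrike"]
            assert ge.n_strides == truth.size
            assert np.max(np.abs(ge.times("heelstrike") - truth)) <= 1.0 / FS + 1e-9


def make_events(ms_times, foot="left", fs=FS):
    ms = (np.asarray(ms_times) * fs).astype(int)
    return ev.GaitEvents(foot, ms - 20, ms, ms + 20, fs)


class TestSegmentWalking:
    def test_single_large_gap_splits_in_two(self):
        times = np.concatenate([np.arange(0, 10, 1.1), np.arange(13, 23, 1.1)])
        segs = ev.segment_walking(make_events(times[::2], "left"),
                                  make_events(times[1::2], "right"))
        assert len(segs) == 2

    def test_gap_below_threshold_keeps_one_segment(self):
        times = np.concatenate([np.arange(0, 10, 1.1), np.arange(11.4, 20, 1.1)])
        segs = ev.segment_walking(make_events(times[::2], "left"),
                                  make_events(times[1::2], "right"))
        assert len(segs) == 1

    def test_boundary_exactly_two_seconds_splits(self):
        left = make_events([1.0, 2.0, 3.0, 6.0, 7.0, 8.0], "left")
        right = make_events([1.5, 2.5, 4.0, 6.5, 7.5, 8.5], "right")
        # largest within-run gap is 4.0 -> 6.0 s = 2.0 s exactly
        segs = ev.segment_walking(left, right)
        assert len(segs) == 2

    def test_boundary_just_below_two_seconds_does_not_split(self):
        left = make_events([1.0, 2.0, 3.0, 5.9, 6.9, 7.9], "left")
        right = make_events([1.5, 2.5, 4.0, 6.4, 7.4, 8.4], "right")
        segs = ev.segment_walking(left, right)
        assert len(segs) == 1

    def test_tiny_segments_discarded(self):
        left = make_events([1.0, 2.0, 3.0, 4.0, 10.0], "left")
        right = make_events([1.5, 2.5, 3.5, 4.5, 10.5], "right")
        segs = ev.segment_walking(left, right)
        assert len(segs) == 1   # the 2-stride trailing group is dropped
        assert segs[0].index == 1

    def test_zero_strides_empty(self):
        empty = ev.GaitEvents("left", [], [], [], FS)
        assert ev.segment_walking(empty, empty) == []

    def test_synthetic_trial_segment_bounds(self, trial_led_nf):
        gel = foot_events(trial_led_nf.ankle_left, "left")
        ger = foot_events(trial_led_nf.ankle_right, "right")
        segs = ev.segment_walking(gel, ger)
        truth = trial_led_nf.truth.segment_bounds
        assert len(segs) == len(truth)
        stride_s = 1.0 / 0.9
        for seg, (a, b) in zip(segs, truth):
            assert seg.start_idx / FS == pytest.approx(a, abs=stride_s)
            assert seg.end_idx / FS == pytest.approx(b, abs=stride_s)


def test_event_order_enforced_on_construction():
    with pytest.raises(ValueError, match="order"):
        ev.GaitEvents("left", [10], [5], [20], FS)


def test_noisy_trial_full_recall(trial_led_noisy):
    """Default gyro noise must not cost strides or create spurious ones."""
    for foot, trace in (("left", trial_led_noisy.ankle_left),
                        ("right", trial_led_noisy.ankle_right)):
        ge = foot_events(trace, foot)
        assert ge.n_strides == trial_led_noisy.truth.event_times[foot]["midswing"].size
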
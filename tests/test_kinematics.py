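"""Polar conversion, trace repair and angle epoching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polardecode import (KinematicsTrace, PolarTrace, ProtocolConfig,
                         fit_circle_center, repair_outliers, resample_uniform,
                         simulate_trajectory, synchronize_and_epoch, to_polar,
                         trace_to_angle_epoch)
from polardecode.synthetic import TWO_PI, target_angle


class TestToPolar:
    def test_printed_special_cases(self):
        assert to_polar(1.0, 0.0) == 0.0
        assert to_polar(0.0, 1.0) == pytest.approx(0.5 * np.pi, abs=0)
        assert to_polar(0.0, -1.0) == pytest.approx(1.5 * np.pi, abs=0)
        # measure-zero negative-axis case resolves through the pi branch
        assert to_polar(-1.0, 0.0) == pytest.approx(np.pi, abs=0)

    @pytest.mark.parametrize("x, y, expected", [
        (1, 1, np.pi / 4), (-1, 1, 3 * np.pi / 4),
        (-1, -1, 5 * np.pi / 4), (1, -1, 7 * np.pi / 4),
    ])
    def test_quadrant_identities(self, x, y, expected):
        assert to_polar(x, y) == pytest.approx(expected, abs=1e-15)

    def test_origin_is_rejected(self):
        with pytest.raises(ValueError):
            to_polar(0.0, 0.0)
        with pytest.raises(ValueError):
            to_polar(np.array([1.0, 0.0]), np.array([1.0, 0.0]))

    def test_round_trip_inverts_to_machine_precision(self, rng):
        theta = rng.uniform(0, TWO_PI, 10_000)
        r = rng.uniform(0.1, 20.0, theta.size)
        recovered = to_polar(r * np.cos(theta), r * np.sin(theta))
        circ_err = np.abs(np.angle(np.exp(1j * (recovered - theta))))
        assert circ_err.max() < 1e-12

    @given(st.floats(-100, 100), st.floats(-100, 100))
    @settings(max_examples=200, deadline=None)
    def test_output_always_in_half_open_range(self, x, y):
        if x == 0 and y == 0:
            return
        theta = to_polar(x, y)
        assert 0.0 <= theta < TWO_PI


class TestResample:
    def test_linear_midpoint(self):
        trace = KinematicsTrace(timestamps=np.array([0.0, 1.0]),
                                x=np.array([0.0, 10.0]), y=np.array([0.0, 0.0]))
        out = resample_uniform(trace, 1000.0)
        i = np.argmin(np.abs(out.timestamps - 0.5))
        assert out.x[i] == pytest.approx(5.0, abs=1e-9)

    def test_identity_on_already_uniform_input(self):
        t = np.arange(2000) / 1000.0
        trace = KinematicsTrace(timestamps=t, x=np.sin(t), y=np.cos(t))
        out = resample_uniform(trace, 1000.0)
        assert np.allclose(out.x, trace.x, atol=1e-12)
        assert out.timestamps.size == trace.timestamps.size

    def test_irregular_trace_resampled_close_to_analytic_circle(self):
        p = ProtocolConfig()
        trace = simulate_trajectory(p, motor_noise_sd=0.0, lag_s=0.0, seed=5,
                                    dropout_expected=0.0)
        out = resample_uniform(trace, 1000.0)
        rate = 1.0 / np.diff(out.timestamps)
        assert np.allclose(rate, 1000.0, atol=1e-6)
        theta = target_angle(out.timestamps, p)
        err = np.hypot(out.x - p.radius_cm * np.cos(theta),
                       out.y - p.radius_cm * np.sin(theta))
        # interpolation across the start/stop velocity kinks is bounded by
        # one camera interval of arc; elsewhere only the tiny sagitta remains
        assert err.max() < 0.05
        t = out.timestamps
        interior = (np.abs(t - p.move_onset_s) > 0.01) & \
                   (np.abs(t - p.move_offset_s) > 0.01)
        assert err[interior].max() < 1e-3

    def test_non_monotone_timestamps_rejected(self):
        with pytest.raises(ValueError):
            KinematicsTrace(timestamps=np.array([0.0, 0.2, 0.1]),
                            x=np.zeros(3), y=np.zeros(3))


class TestRepair:
    def _circle_trace(self, n=500):
        t = np.arange(n) / 500.0
        return KinematicsTrace(timestamps=t, x=10 * np.cos(t), y=10 * np.sin(t))

    def test_clean_trace_unchanged(self):
        trace = self._circle_trace()
        out, report = repair_outliers(trace)
        assert report.n_repaired == 0
        assert np.array_equal(out.x, trace.x)

    def test_injected_spike_restored_to_neighbour_mean(self):
        trace = self._circle_trace()
        trace.x[100] += 50.0
        out, report = repair_outliers(trace, jump_threshold=3.0)
        assert report.n_repaired >= 1
        assert abs(out.x[100] - 0.5 * (out.x[99] + out.x[101])) < 1e-12
        assert abs(out.x[100] - 10 * np.cos(100 / 500)) < 0.1

    def test_boundary_spike_takes_single_neighbour(self):
        trace = self._circle_trace()
        trace.x[0] += 50.0
        out, _ = repair_outliers(trace, jump_threshold=3.0)
        assert out.x[0] == pytest.approx(out.x[1])

    def test_long_run_is_bridged_and_flagged(self):
        trace = self._circle_trace()
        trace.x[200:215] += 50.0
        out, report = repair_outliers(trace, jump_threshold=3.0, max_run=5)
        assert report.long_runs  # flagged
        # bridged values lie between the surrounding good samples
        assert np.abs(out.x[200:215] - 10 * np.cos(np.arange(200, 215) / 500)).max() < 0.5


def test_circle_fit_recovers_centre_and_radius(rng):
    theta = rng.uniform(0, TWO_PI, 300)
    x = 3.0 + 10.0 * np.cos(theta) + rng.normal(0, 0.05, 300)
    y = -2.0 + 10.0 * np.sin(theta) + rng.normal(0, 0.05, 300)
    cx, cy, r = fit_circle_center(x, y)
    assert abs(cx - 3.0) < 0.05 and abs(cy + 2.0) < 0.05 and abs(r - 10.0) < 0.05


class TestEpoching:
    def test_default_protocol_gives_700_label_samples(self):
        p = ProtocolConfig()
        trace = simulate_trajectory(p, seed=2)
        epoch, _ = trace_to_angle_epoch(
            trace, {"move_on_s": p.move_onset_s, "move_off_s": p.move_offset_s})
        assert epoch.theta.shape == (700,)
        assert epoch.theta.min() >= 0 and epoch.theta.max() < TWO_PI

    def test_noiseless_clockwise_trial_decreases_monotonically(self):
        p = ProtocolConfig()
        trace = simulate_trajectory(p, motor_noise_sd=0.0, lag_s=0.0, seed=2,
                                    dropout_expected=0.0)
        epoch, _ = trace_to_angle_epoch(
            trace, {"move_on_s": p.move_onset_s, "move_off_s": p.move_offset_s},
            center=(0.0, 0.0))
        t = -0.5 + np.arange(700) / 100.0
        interior = (t > 0.3) & (t < 5.7)
        assert np.all(np.diff(epoch.theta[interior]) < 0)

    def test_epoch_beyond_trace_bounds_names_the_trial(self):
        theta = PolarTrace(timestamps=np.arange(3000) / 1000.0,
                           theta=np.zeros(3000))
        with pytest.raises(ValueError, match="trial 17"):
            synchronize_and_epoch(theta, {"move_on_s": 0.2, "move_off_s": 4.0},
                                  trial_id=17)

    def test_chain_reproduces_analytic_angle_on_noiseless_data(self):
        p = ProtocolConfig()
        trace = simulate_trajectory(p, motor_noise_sd=0.0, lag_s=0.0, seed=3,
                                    dropout_expected=0.0)
        epoch, report = trace_to_angle_epoch(
            trace, {"move_on_s": p.move_onset_s, "move_off_s": p.move_offset_s},
            center=(0.0, 0.0))
        assert report.n_repaired == 0
        t = p.move_onset_s - 0.5 + np.arange(700) / 100.0
        expected = target_angle(t, p)
        circ_err = np.abs(np.angle(np.exp(1j * (epoch.theta - expected))))
        # exclude the filter edge and the wrap point itself
        interior = (t > p.move_onset_s + 0.2) & (t < p.move_offset_s - 0.2)
        assert circ_err[interior].max() < 1e-6


def test_window_centre_equals_circular_mean_for_uniform_rotation():
    """The centre of a window matches its circular mean away from the wrap.

    For an even window length the temporal midpoint falls between samples
    49 and 50, so the circular mean coincides with the interpolated
    mid-sample angle to numerical precision, and the 50th-sample label
    deviates only by the half-sample rotation (~0.005 rad at this speed —
    the practical gap grows with motor noise).
    """
    p = ProtocolConfig()
    t = np.arange(700) / 100.0 - 0.5
    theta = target_angle(t + p.move_onset_s, p)
    omega = TWO_PI / p.rotation_period_s
    half_sample = omega * 0.005
    for start in range(0, 601, 50):
        window = theta[start:start + 100]
        if np.abs(window - np.pi).max() > np.pi - 0.7:  # touches the wrap
            continue
        circ_mean = np.angle(np.exp(1j * window).mean()) % TWO_PI
        midpoint = np.angle(np.exp(1j * window[[49, 50]]).mean()) % TWO_PI
        assert abs(circ_mean - midpoint) < 1e-9
        label = window[49]
        assert abs(circ_mean - label) == pytest.approx(half_sample, abs=1e-9)
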
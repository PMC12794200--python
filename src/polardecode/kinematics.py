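"""Hand-kinematics processing: from camera traces to polar-angle labels.

The decoding target is the polar angle of the hand about the centre of the
circular route, constrained to [0, 2pi) so that a full clockwise rotation
is continuous everywhere except at the start/end point.  The chain is:

    irregular camera trace -> uniform 1 kHz resampling -> outlier repair
    -> centring on the fitted circle centre -> polar conversion
    -> trigger-aligned epoching and 100 Hz downsampling

Angles are never filtered directly: anti-alias filtering and decimation
act on (cos theta, sin theta), which avoids smearing the wrap point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import resample_poly

from .synthetic import TWO_PI, KinematicsTrace


@dataclass
class PolarTrace:
    """Uniformly sampled polar-angle series (rad, [0, 2pi))."""

    timestamps: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.timestamps.shape != self.theta.shape:
            raise ValueError("timestamps and theta must have matching shapes")

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.timestamps)))


@dataclass
class AngleEpoch:
    """Per-trial angle labels at 100 Hz over the analysis epoch.

    The epoch spans the last 0.5 s of preparation, the whole movement
    period and the first 0.5 s of rest (700 samples under the default
    7-s span).
    """

    trial_id: int
    theta: np.ndarray
    rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)


@dataclass
class RepairReport:
    """Bookkeeping from outlier repair."""

    n_repaired: int = 0
    long_runs: list = field(default_factory=list)  # (start, length) bridged runs


def resample_uniform(trace: KinematicsTrace, target_rate: float = 1000.0) -> KinematicsTrace:
    """Linearly interpolate an irregular trace onto a uniform grid.

    The output grid starts at the first input timestamp and steps at
    ``1/target_rate`` up to the last input timestamp.
    """
    if len(trace) < 2:
        raise ValueError("need at least two samples to resample")
    ts = trace.timestamps
    if np.any(np.diff(ts) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    n_out = int(np.floor((ts[-1] - ts[0]) * target_rate)) + 1
    t_new = ts[0] + np.arange(n_out) / target_rate
    return KinematicsTrace(
        timestamps=t_new,
        x=np.interp(t_new, ts, trace.x),
        y=np.interp(t_new, ts, trace.y),
    )


def repair_outliers(
    trace: KinematicsTrace,
    jump_threshold: float = 3.0,
    max_run: int = 5,
) -> tuple[KinematicsTrace, RepairReport]:
    """Replace tracking-loss outliers with estimates from their neighbours.

    A sample is an outlier when it sits more than ``jump_threshold`` (cm)
    from a rolling-median baseline of the trace — a deviation far beyond
    any physiological hand excursion between camera frames.  A single
    outlier is replaced by the mean of its two neighbours (its single
    neighbour at a trace boundary); a run of consecutive outliers is
    bridged linearly between the surrounding good samples, and runs
    longer than ``max_run`` are additionally flagged in the report.
    Detection and repair repeat until the trace is jump-free.
    """
    from scipy.ndimage import median_filter

    x = trace.x.copy()
    y = trace.y.copy()
    n = x.size
    report = RepairReport()
    if n < 3:
        return KinematicsTrace(trace.timestamps, x, y), report
    kernel = min(max(4 * max_run + 11, 31), (n // 2) * 2 - 1)

    for _ in range(3):
        base_x = median_filter(x, size=kernel, mode="reflect")
        base_y = median_filter(y, size=kernel, mode="reflect")
        mask = np.hypot(x - base_x, y - base_y) > jump_threshold
        if not mask.any():
            break
        report.n_repaired += int(mask.sum())
        padded = np.concatenate(([False], mask, [False]))
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        stops = np.flatnonzero(padded[:-1] & ~padded[1:])
        for start, stop in zip(starts, stops):
            length = stop - start
            if length > max_run:
                report.long_runs.append((int(start), int(length)))
            if start == 0 and stop == n:
                break
            if start == 0:
                x[:stop] = x[stop]
                y[:stop] = y[stop]
            elif stop == n:
                x[start:] = x[start - 1]
                y[start:] = y[start - 1]
            elif length == 1:
                x[start] = 0.5 * (x[start - 1] + x[stop])
                y[start] = 0.5 * (y[start - 1] + y[stop])
            else:
                ts = trace.timestamps
                span = [ts[start - 1], ts[stop]]
                x[start:stop] = np.interp(ts[start:stop], span, [x[start - 1], x[stop]])
                y[start:stop] = np.interp(ts[start:stop], span, [y[start - 1], y[stop]])

    return KinematicsTrace(trace.timestamps, x, y), report


def fit_circle_center(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares (Kasa) circle fit; returns (cx, cy, radius)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    radius = float(np.sqrt(c + cx**2 + cy**2))
    return float(cx), float(cy), radius


def to_polar(x, y):
    """Quadrant-correct polar angle in [0, 2pi) of centred coordinates.

    Implements the piecewise arctangent with the special cases
    theta = 0 for (x >= 0, y = 0), pi/2 for (x = 0, y > 0) and 3pi/2 for
    (x = 0, y < 0); the measure-zero case (x < 0, y = 0) falls on the
    pi + arctan branch and yields pi.  Vectorized; the origin is undefined
    and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((x == 0) & (y == 0)):
        raise ValueError("polar angle undefined at the origin")
    theta = np.mod(np.arctan2(y, x), TWO_PI)
    # guard against a rounding hit on exactly 2*pi
    theta = np.where(theta >= TWO_PI, 0.0, theta)
    if theta.ndim == 0:
        return float(theta)
    return theta


def _decimate_angle(theta: np.ndarray, up: int, down: int) -> np.ndarray:
    """Rate-convert an angle series through its unit-circle embedding."""
    c = resample_poly(np.cos(theta), up, down)
    s = resample_poly(np.sin(theta), up, down)
    return to_polar(c, s)


def synchronize_and_epoch(
    theta_trace: PolarTrace,
    triggers: dict,
    epoch_pad_s: float = 0.5,
    out_rate_hz: float = 100.0,
    trial_id: int = 0,
) -> AngleEpoch:
    """Cut one trial's angle labels and downsample them to 100 Hz.

    ``triggers`` holds movement onset/offset times in seconds (keys
    ``move_on_s``, ``move_off_s``) on the trace's clock.  The epoch spans
    ``[move_on - pad, move_off + pad]``; the 1 kHz angle series is
    decimated via its cos/sin embedding with polyphase anti-aliasing.
    """
    rate = theta_trace.rate_hz
    t0 = theta_trace.timestamps[0]
    start_s = triggers["move_on_s"] - epoch_pad_s
    stop_s = triggers["move_off_s"] + epoch_pad_s
    i0 = int(round((start_s - t0) * rate))
    n_in = int(round((stop_s - start_s) * rate))
    if i0 < 0 or i0 + n_in > theta_trace.theta.size:
        raise ValueError(
            f"trial {trial_id}: epoch [{start_s:.3f}, {stop_s:.3f}] s exceeds "
            f"the kinematics trace span"
        )
    seg = theta_trace.theta[i0 : i0 + n_in]
    up = int(round(out_rate_hz))
    down = int(round(rate))
    g = np.gcd(up, down)
    theta_ds = _decimate_angle(seg, up // g, down // g)
    return AngleEpoch(trial_id=trial_id, theta=theta_ds, rate_hz=out_rate_hz)


def trace_to_angle_epoch(
    trace: KinematicsTrace,
    triggers_s: dict,
    trial_id: int = 0,
    center: tuple[float, float] | None = None,
    jump_threshold: float = 3.0,
    epoch_pad_s: float = 0.5,
) -> tuple[AngleEpoch, RepairReport]:
    """Full per-trial chain: resample, repair, centre, polar, epoch."""
    uniform = resample_uniform(trace, 1000.0)
    repaired, report = repair_outliers(uniform, jump_threshold=jump_threshold)
    if center is None:
        cx, cy, _ = fit_circle_center(repaired.x, repaired.y)
    else:
        cx, cy = center
    theta = to_polar(repaired.x - cx, repaired.y - cy)
    ptrace = PolarTrace(timestamps=repaired.timestamps, theta=theta)
    epoch = synchronize_and_epoch(ptrace, triggers_s, epoch_pad_s=epoch_pad_s,
                                  trial_id=trial_id)
    return epoch, report
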
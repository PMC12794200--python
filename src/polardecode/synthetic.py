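"""Synthetic bimanual circular-tracking datasets (kinematics + EEG).

The real recordings this pipeline was designed around are not publicly
deposited, so this module generates surrogate subject datasets with the
statistical structure the decoding analysis assumes:

* a session/trial protocol (20 sessions x 10 trials; 1 s preparation,
  6 s movement, 2 s rest per trial) with clockwise constant-speed circular
  target motion (10 cm radius, one rotation in 6 s);
* hand tracking as a first-order lagged pursuit of the target with smooth
  motor noise, sampled by a camera whose frame rate jitters between 400
  and 600 Hz and which occasionally loses the marker (far-off outliers);
* EEG at 256 Hz containing a 1/f background, angle-locked low-frequency
  components over sensorimotor channels, alpha/beta oscillations whose
  envelope drops during movement (ERD), a slow pre-movement negativity
  (MRCP), frontal blink deflections, and 50 Hz line interference.

All randomness flows from one master seed: trial ``(s, k)`` of a subject
draws its generators from ``SeedSequence([master, s, k, purpose])`` so any
trial can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .channels import CHANNELS, FRONTAL, MOTOR, MOTOR_NEIGHBOURS, N_CHANNELS, indices

TWO_PI = 2.0 * np.pi


class ConfigurationError(ValueError):
    """Raised when a protocol or encoding configuration is invalid."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ProtocolConfig:
    """Timing and geometry of the circular-tracking task."""

    n_sessions: int = 20
    trials_per_session: int = 10
    prep_s: float = 1.0
    move_s: float = 6.0
    rest_s: float = 2.0
    inter_session_rest_s: float = 30.0
    rotation_period_s: float = 6.0
    radius_cm: float = 10.0
    direction: str = "clockwise"
    eeg_rate_hz: float = 256.0
    n_channels: int = N_CHANNELS
    camera_rate_range_hz: tuple[float, float] = (400.0, 600.0)

    def __post_init__(self) -> None:
        for name in ("prep_s", "move_s", "rest_s", "rotation_period_s",
                     "radius_cm", "eeg_rate_hz"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.direction not in ("clockwise", "counterclockwise"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        lo, hi = self.camera_rate_range_hz
        if not 0 < lo <= hi:
            raise ConfigurationError("camera_rate_range_hz must be 0 < low <= high")
        if self.n_sessions <= 0 or self.trials_per_session <= 0:
            raise ConfigurationError("session/trial counts must be positive")

    @property
    def trial_s(self) -> float:
        return self.prep_s + self.move_s + self.rest_s

    @property
    def n_trials(self) -> int:
        return self.n_sessions * self.trials_per_session

    @property
    def move_onset_s(self) -> float:
        return self.prep_s

    @property
    def move_offset_s(self) -> float:
        return self.prep_s + self.move_s


@dataclass
class EncodingConfig:
    """Amplitudes and rates of the simulated EEG components (uV unless noted)."""

    angle_gain: float = 5.0
    channel_topography: np.ndarray | None = None  # (2, n_channels) cos/sin weights
    erd_depth: float = 0.5
    mrcp_amplitude: float = 8.0
    blink_rate_hz: float = 0.08
    blink_amplitude_uv: float = 150.0
    line_noise_uv: float = 2.0
    background_scale: float = 10.0
    alpha_uv: float = 4.0
    beta_uv: float = 2.0
    motor_noise_sd_cm: float = 0.3
    lag_s: float = 0.1
    dropout_expected_per_trial: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ConfigurationError("erd_depth must lie in [0, 1]")
        for name in ("angle_gain", "mrcp_amplitude", "blink_rate_hz",
                     "blink_amplitude_uv", "line_noise_uv", "background_scale",
                     "alpha_uv", "beta_uv", "motor_noise_sd_cm"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class KinematicsTrace:
    """Irregularly sampled 2-D hand position (cm) with timestamps (s)."""

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.timestamps.shape == self.x.shape == self.y.shape):
            raise ValueError("timestamps, x and y must have matching shapes")
        if self.timestamps.size >= 2 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass
class TrialRecording:
    """One trial's raw EEG (channels x samples, uV), triggers and kinematics."""

    eeg: np.ndarray
    trigger_onsets: dict  # sample indices: prep, move_on, move_off
    kinematics: KinematicsTrace
    trial_id: int
    session_id: int

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        if self.eeg.ndim != 2:
            raise ValueError("eeg must be channels x samples")


# ---------------------------------------------------------------------------
# target and hand trajectories
# ---------------------------------------------------------------------------

def target_angle(t: np.ndarray, protocol: ProtocolConfig) -> np.ndarray:
    """Ground-truth target angle (rad, [0, 2pi)) at times ``t`` in the trial.

    The target sits at the rightmost point (angle 0) during preparation,
    sweeps one full rotation during movement, and rests at angle 0 after.
    Clockwise motion is generated as ``(2pi - w t) mod 2pi`` so the angle is
    continuous inside the movement and the wrap sits at the start/end point.
    """
    t = np.asarray(t, dtype=float)
    phase = np.clip((t - protocol.move_onset_s) / protocol.rotation_period_s, 0.0, None)
    phase = np.minimum(phase, protocol.move_s / protocol.rotation_period_s)
    if protocol.direction == "clockwise":
        theta = np.mod(TWO_PI - TWO_PI * phase, TWO_PI)
    else:
        theta = np.mod(TWO_PI * phase, TWO_PI)
    return theta


def simulate_trajectory(
    protocol: ProtocolConfig,
    motor_noise_sd: float = 0.3,
    lag_s: float = 0.1,
    seed: int = 0,
    dropout_expected: float = 0.05,
) -> KinematicsTrace:
    """Simulate one trial's camera-sampled hand trace.

    The hand pursues the target through a first-order lag of time constant
    ``lag_s`` and is perturbed by smooth additive noise with standard
    deviation ``motor_noise_sd`` (cm) per axis.  Sample intervals are drawn
    uniformly from the reciprocal camera-rate range; with expectation
    ``dropout_expected`` per trial a short run of samples is replaced by
    far-off outliers, emulating momentary tracking loss.
    """
    if motor_noise_sd < 0:
        raise ConfigurationError("motor_noise_sd must be non-negative")
    if lag_s < 0:
        raise ConfigurationError("lag_s must be non-negative")
    rng = np.random.default_rng(seed)
    lo, hi = protocol.camera_rate_range_hz
    duration = protocol.trial_s

    # draw enough jittered intervals to cover the trial, then trim
    n_max = int(np.ceil(duration * hi)) + 2
    dts = rng.uniform(1.0 / hi, 1.0 / lo, size=n_max)
    ts = np.concatenate(([0.0], np.cumsum(dts)))
    ts = ts[: int(np.searchsorted(ts, duration)) + 1]

    theta = target_angle(ts, protocol)
    tx = protocol.radius_cm * np.cos(theta)
    ty = protocol.radius_cm * np.sin(theta)

    if lag_s > 0:
        hx = np.empty_like(tx)
        hy = np.empty_like(ty)
        hx[0], hy[0] = tx[0], ty[0]
        alpha = 1.0 - np.exp(-np.diff(ts) / lag_s)
        for i in range(1, ts.size):
            hx[i] = hx[i - 1] + alpha[i - 1] * (tx[i] - hx[i - 1])
            hy[i] = hy[i - 1] + alpha[i - 1] * (ty[i] - hy[i - 1])
    else:
        hx, hy = tx.copy(), ty.copy()

    if motor_noise_sd > 0:
        # smooth (~20 ms) noise rescaled to the requested per-axis SD
        for arr in (hx, hy):
            noise = gaussian_filter1d(rng.standard_normal(ts.size), sigma=10.0)
            sd = noise.std()
            if sd > 0:
                arr += motor_noise_sd / sd * noise

    n_drop = rng.poisson(dropout_expected)
    for _ in range(n_drop):
        start = rng.integers(1, max(2, ts.size - 4))
        run = int(rng.integers(1, 4))
        direction = rng.uniform(0, TWO_PI)
        hx[start : start + run] += 50.0 * np.cos(direction)
        hy[start : start + run] += 50.0 * np.sin(direction)

    return KinematicsTrace(timestamps=ts, x=hx, y=hy)


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def default_topography(n_channels: int = N_CHANNELS) -> np.ndarray:
    """Default (2, n_channels) projection of cos/sin angle components.

    The cosine component loads mostly on left sensorimotor cortex (C3),
    the sine component on the right (C4), both sharing a Cz contribution —
    a stylized bilateral hand-movement topography.
    """
    w = np.zeros((2, n_channels))
    w[0, indices(("C3",))] = 1.0
    w[0, indices(("Cz",))] = 0.5
    w[0, indices(("FC1", "CP1"))] = 0.4
    w[0, indices(("FC5", "CP5"))] = 0.3
    w[0, indices(("F3", "P3"))] = 0.2
    w[1, indices(("C4",))] = 1.0
    w[1, indices(("Cz",))] = 0.5
    w[1, indices(("FC2", "CP2"))] = 0.4
    w[1, indices(("FC6", "CP6"))] = 0.3
    w[1, indices(("F4", "P4"))] = 0.2
    return w


def _motor_weights() -> np.ndarray:
    w = np.zeros(N_CHANNELS)
    w[indices(MOTOR)] = 1.0
    w[indices(MOTOR_NEIGHBOURS)] = 0.5
    return w


def _frontal_weights() -> np.ndarray:
    w = np.zeros(N_CHANNELS)
    w[indices(("Fp1", "Fp2"))] = 1.0
    w[indices(("F7", "F8"))] = 0.4
    w[indices(("F3", "Fz", "F4"))] = 0.3
    return w


def _central_weights() -> np.ndarray:
    w = np.zeros(N_CHANNELS)
    w[indices(("Cz",))] = 1.0
    w[indices(("C3", "C4"))] = 0.8
    w[indices(("FC1", "FC2", "CP1", "CP2"))] = 0.5
    return w


_MIX_CACHE: dict = {}


def _spatial_mixing(n_channels: int, sigma_m: float = 0.04) -> np.ndarray:
    """Volume-conduction-like mixing: Gaussian kernel over scalp distance.

    Neighbouring electrodes share sources, giving the strong short-range
    correlation real scalp EEG shows.  Rows are unit-norm so per-channel
    variance is preserved.  Falls back to mild random mixing when no
    montage of the requested size is available.
    """
    key = (n_channels, sigma_m)
    if key not in _MIX_CACHE:
        if n_channels == N_CHANNELS:
            from .channels import montage_positions

            pos = montage_positions()
            d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
            mix = np.exp(-d2 / (2.0 * sigma_m ** 2))
        else:
            mix = np.eye(n_channels) + 0.3 * np.ones((n_channels, n_channels)) / n_channels
        mix /= np.linalg.norm(mix, axis=1, keepdims=True)
        _MIX_CACHE[key] = mix
    return _MIX_CACHE[key]


def pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
               rate_hz: float) -> np.ndarray:
    """Spatially correlated 1/f background with unit per-channel SD.

    Source signals are amplitude-modulated by a slow (~0.3 s) envelope,
    reproducing the super-Gaussian amplitude statistics of scalp EEG
    (plain Gaussian sources would also make blind source separation
    ill-posed).
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate_hz)
    profile = 1.0 / np.maximum(freqs, 1.0)  # flat below 1 Hz, 1/f above
    profile[0] = 0.0
    spectra = np.fft.rfft(rng.standard_normal((n_channels, n_samples)), axis=1)
    noise = np.fft.irfft(spectra * profile, n=n_samples, axis=1)
    env = gaussian_filter1d(rng.standard_normal((n_channels, n_samples)),
                            sigma=0.3 * rate_hz, axis=1)
    env /= env.std(axis=1, keepdims=True) + 1e-30
    noise *= 1.0 + np.abs(env)
    noise = _spatial_mixing(n_channels) @ noise
    noise /= noise.std(axis=1, keepdims=True)
    return noise


def _smooth_gate(t: np.ndarray, on: float, off: float, ramp_s: float = 0.25) -> np.ndarray:
    """Raised-cosine gate: 0 outside [on-ramp, off+ramp], 1 inside [on, off]."""
    gate = np.zeros_like(t)
    inside = (t >= on) & (t <= off)
    gate[inside] = 1.0
    rise = (t >= on - ramp_s) & (t < on)
    gate[rise] = 0.5 * (1 + np.cos(np.pi * (on - t[rise]) / ramp_s))
    fall = (t > off) & (t <= off + ramp_s)
    gate[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - off) / ramp_s))
    return gate


def _angle_from_trace(trace: KinematicsTrace, t_eeg: np.ndarray) -> np.ndarray:
    """Hand angle at EEG sample times, robust to injected tracking outliers."""
    x = trace.x.copy()
    y = trace.y.copy()
    # internal repair: a camera outlier is not hand motion, so it must not
    # leak into the neural encoding
    r = np.hypot(x, y)
    med = np.median(r)
    bad = np.abs(r - med) > 10.0
    good = ~bad
    if bad.any() and good.sum() >= 2:
        x[bad] = np.interp(trace.timestamps[bad], trace.timestamps[good], x[good])
        y[bad] = np.interp(trace.timestamps[bad], trace.timestamps[good], y[good])
    xi = np.interp(t_eeg, trace.timestamps, x)
    yi = np.interp(t_eeg, trace.timestamps, y)
    return np.mod(np.arctan2(yi, xi), TWO_PI)


def simulate_eeg(
    trace: KinematicsTrace,
    protocol: ProtocolConfig,
    encoding: EncodingConfig,
    seed: int | None = None,
    trial_id: int = 0,
    session_id: int = 0,
) -> TrialRecording:
    """Synthesize one trial of 32-channel EEG consistent with ``trace``.

    Components, all additive on a pink-noise background:
    angle-locked cos/sin of the hand angle projected through the encoding
    topography (movement period only); alpha (10 Hz) and beta (20 Hz)
    oscillations over sensorimotor channels whose envelope drops by
    ``erd_depth`` during movement; a slow negativity ramping in from 1 s
    before movement onset at central channels; Poisson-timed frontal
    blinks; and a 50 Hz line-noise sinusoid.
    """
    fs = protocol.eeg_rate_hz
    duration = protocol.trial_s
    if trace.timestamps[-1] < duration - 1.0 / min(protocol.camera_rate_range_hz):
        raise ValueError("kinematics trace does not cover the trial timeline")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    # independent generator per component: toggling one component off leaves
    # every other component bit-identical under the same seed
    root = np.random.SeedSequence(encoding.seed if seed is None else seed)
    rng_pink, rng_osc, rng_blink, rng_line = map(np.random.default_rng,
                                                 root.spawn(4))

    eeg = encoding.background_scale * pink_noise(rng_pink, protocol.n_channels, n, fs)

    move_on, move_off = protocol.move_onset_s, protocol.move_offset_s
    move_mask = ((t >= move_on) & (t <= move_off)).astype(float)

    if encoding.angle_gain > 0:
        theta = _angle_from_trace(trace, t)
        topo = encoding.channel_topography
        if topo is None:
            topo = default_topography(protocol.n_channels)
        comp = np.vstack([np.cos(theta), np.sin(theta)]) * move_mask
        eeg += encoding.angle_gain * (np.asarray(topo).T @ comp)

    if encoding.alpha_uv > 0 or encoding.beta_uv > 0:
        env = 1.0 - encoding.erd_depth * _smooth_gate(t, move_on, move_off)
        motor_w = _motor_weights()
        phases = rng_osc.uniform(0, TWO_PI, size=(2, protocol.n_channels))
        osc = (encoding.alpha_uv * np.sin(TWO_PI * 10.0 * t + phases[0][:, None])
               + encoding.beta_uv * np.sin(TWO_PI * 20.0 * t + phases[1][:, None]))
        eeg += motor_w[:, None] * osc * env

    if encoding.mrcp_amplitude > 0:
        ramp = np.zeros(n)
        pre = (t >= move_on - 1.0) & (t < move_on)
        ramp[pre] = (t[pre] - (move_on - 1.0)) / 1.0
        ramp[(t >= move_on) & (t <= move_off)] = 1.0
        post = (t > move_off) & (t <= move_off + 0.5)
        ramp[post] = 1.0 - (t[post] - move_off) / 0.5
        eeg -= encoding.mrcp_amplitude * np.outer(_central_weights(), ramp)

    if encoding.blink_rate_hz > 0 and encoding.blink_amplitude_uv > 0:
        n_blinks = rng_blink.poisson(encoding.blink_rate_hz * duration)
        frontal_w = _frontal_weights()
        for _ in range(n_blinks):
            centre = rng_blink.uniform(0.2, duration - 0.2)
            bump = np.exp(-0.5 * ((t - centre) / 0.06) ** 2)
            eeg += encoding.blink_amplitude_uv * np.outer(frontal_w, bump)

    if encoding.line_noise_uv > 0:
        phase = rng_line.uniform(0, TWO_PI)
        amps = encoding.line_noise_uv * rng_line.uniform(0.8, 1.2, protocol.n_channels)
        eeg += np.outer(amps, np.sin(TWO_PI * 50.0 * t + phase))

    triggers = {
        "prep": 0,
        "move_on": int(round(move_on * fs)),
        "move_off": int(round(move_off * fs)),
    }
    return TrialRecording(eeg=eeg, trigger_onsets=triggers, kinematics=trace,
                          trial_id=trial_id, session_id=session_id)


# ---------------------------------------------------------------------------
# subject-level generation
# ---------------------------------------------------------------------------

def trial_seeds(master_seed: int, session: int, trial: int) -> tuple[int, int]:
    """Deterministic (trajectory, eeg) seeds for one trial of a subject."""
    state = np.random.SeedSequence([master_seed, session, trial]).generate_state(2)
    return int(state[0]), int(state[1])


def simulate_subject(
    protocol: ProtocolConfig,
    encoding: EncodingConfig,
) -> list[TrialRecording]:
    """Generate all ``n_sessions x trials_per_session`` trials of a subject."""
    trials: list[TrialRecording] = []
    trial_counter = 0
    for s in range(protocol.n_sessions):
        for k in range(protocol.trials_per_session):
            seed_traj, seed_eeg = trial_seeds(encoding.seed, s, k)
            trace = simulate_trajectory(
                protocol,
                motor_noise_sd=encoding.motor_noise_sd_cm,
                lag_s=encoding.lag_s,
                seed=seed_traj,
                dropout_expected=encoding.dropout_expected_per_trial,
            )
            trials.append(
                simulate_eeg(trace, protocol, encoding, seed=seed_eeg,
                             trial_id=trial_counter, session_id=s)
            )
            trial_counter += 1
    return trials


def concatenate_session(trials: Sequence[TrialRecording]) -> tuple[np.ndarray, list[dict]]:
    """Stack one session's trials into continuous EEG plus a trigger table.

    Returns ``(eeg, triggers)`` where ``triggers[i]`` holds the absolute
    sample indices of trial ``i``'s preparation onset, movement onset and
    movement offset within the concatenated array.
    """
    if not trials:
        raise ValueError("empty session")
    eeg = np.concatenate([tr.eeg for tr in trials], axis=1)
    triggers = []
    offset = 0
    for tr in trials:
        triggers.append({
            "trial_id": tr.trial_id,
            "prep": offset + tr.trigger_onsets["prep"],
            "move_on": offset + tr.trigger_onsets["move_on"],
            "move_off": offset + tr.trigger_onsets["move_off"],
        })
        offset += tr.eeg.shape[1]
    return eeg, triggers
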
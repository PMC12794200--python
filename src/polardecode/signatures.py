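"""Movement-related neural signatures: MRCP averages and ERSP maps.

These analyses validate that the (synthetic or recorded) EEG carries the
electrophysiology the decoding paradigm expects: a slow negative
potential shift (MRCP, 0.1-4 Hz) building up from about 1 s before
movement onset, and alpha/beta event-related desynchronization (ERD)
during movement, both strongest over sensorimotor cortex (C3/Cz/C4).

ERSP uses Morlet wavelet convolution with log-domain baseline
normalization: power is converted to dB and the mean dB over the
baseline interval is subtracted per frequency, so the baseline mean is
0 dB by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .channels import channel_index
from .preprocessing import bandpass_zero_phase


@dataclass
class MrcpResult:
    """Across-trial mean slow potential at one channel with 95% CI."""

    channel: str
    time: np.ndarray          # s relative to movement onset
    mean: np.ndarray          # uV
    ci95: np.ndarray          # (2, T) lower/upper band, uV


@dataclass
class ErspResult:
    """Across-trial time-frequency power change (dB) at one channel."""

    channel: str
    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray         # (n_freqs, T), dB relative to baseline


def compute_mrcp(
    epochs: np.ndarray,
    times: np.ndarray,
    channels,
    fs: float = 100.0,
    band: tuple[float, float] = (0.1, 4.0),
) -> list[MrcpResult]:
    """Per-channel MRCP: band-filtered across-trial mean with t-interval.

    ``epochs`` is (n_trials, n_channels, n_samples); ``times`` gives the
    epoch clock in seconds relative to movement onset.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.shape[0] < 2:
        raise ValueError("MRCP needs at least two epochs")
    n = epochs.shape[0]
    out = []
    for name in channels:
        ci = channel_index(name)
        # transition width capped by the epoch length (short 7-s epochs)
        filtered = bandpass_zero_phase(epochs[:, ci, :], fs, band, transition_hz=0.5)
        mean = filtered.mean(axis=0)
        sem = filtered.std(axis=0, ddof=1) / np.sqrt(n)
        half = sem * stats.t.ppf(0.975, n - 1)
        out.append(MrcpResult(channel=name, time=np.asarray(times),
                              mean=mean, ci95=np.vstack([mean - half, mean + half])))
    return out


def compute_ersp(
    epochs: np.ndarray,
    times: np.ndarray,
    channels,
    fs: float = 100.0,
    freq_range: tuple[float, float] = (4.0, 30.0),
    n_freqs: int = 27,
    baseline: tuple[float, float] = (-1.0, 0.0),
) -> list[ErspResult]:
    """Per-channel ERSP from Morlet wavelets, dB relative to baseline.

    Wavelet cycles scale as freq/2 bounded to [3, 10].  Baseline
    normalization is done in the log domain: the mean dB over the
    baseline interval is subtracted per frequency.
    """
    from mne.time_frequency import tfr_array_morlet

    epochs = np.asarray(epochs, dtype=float)
    times = np.asarray(times)
    b0, b1 = baseline
    bmask = (times >= b0) & (times < b1)
    if times[0] > b0 or not bmask.any():
        raise ValueError(f"baseline {baseline} s lies outside the epoch "
                         f"[{times[0]:.2f}, {times[-1]:.2f}] s")
    idx = [channel_index(name) for name in channels]
    freqs = np.linspace(freq_range[0], freq_range[1], n_freqs)
    n_cycles = np.clip(freqs / 2.0, 3.0, 10.0)
    power = tfr_array_morlet(epochs[:, idx, :], sfreq=fs, freqs=freqs,
                             n_cycles=n_cycles, output="power", verbose="error")
    mean_power = power.mean(axis=0)  # (n_sel, n_freqs, T)
    out = []
    for i, name in enumerate(channels):
        db = 10.0 * np.log10(mean_power[i] + 1e-30)
        db -= db[:, bmask].mean(axis=1, keepdims=True)
        out.append(ErspResult(channel=name, freqs=freqs, times=times, power=db))
    return out


def channel_voltage_summary(
    epochs: np.ndarray,
    times: np.ndarray,
    timepoints,
) -> np.ndarray:
    """Across-trial mean voltage per channel at the requested times.

    The numeric substrate of a topographic-map sequence: returns an
    (n_channels, n_timepoints) array (map rendering is out of scope).
    """
    epochs = np.asarray(epochs, dtype=float)
    times = np.asarray(times)
    timepoints = np.atleast_1d(np.asarray(timepoints, dtype=float))
    if timepoints.min() < times[0] or timepoints.max() > times[-1]:
        raise ValueError("requested timepoint outside the epoch")
    cols = [np.argmin(np.abs(times - tp)) for tp in timepoints]
    return epochs.mean(axis=0)[:, cols]


def erd_band_power(ersp: ErspResult, band: tuple[float, float],
                   interval: tuple[float, float]) -> float:
    """Mean dB change in a frequency band over a time interval."""
    fmask = (ersp.freqs >= band[0]) & (ersp.freqs <= band[1])
    tmask = (ersp.times >= interval[0]) & (ersp.times <= interval[1])
    return float(ersp.power[np.ix_(fmask, tmask)].mean())
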
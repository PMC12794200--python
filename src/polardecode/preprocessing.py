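"""EEG cleaning chain: notch, band-pass, channel repair, CAR, ICA, epoching.

The chain runs in a fixed order on each session's continuous recording:

    50 Hz notch -> 0.1-30 Hz zero-phase FIR band-pass -> bad-channel
    detection + spherical-spline interpolation -> common average reference
    -> per-session ICA with ocular-component removal -> trigger-aligned
    epoching with pre-movement baseline correction and 100 Hz downsampling

ICA follows the dual-filter recipe: the unmixing matrix is estimated on a
1 Hz high-passed copy (ICA quality) and applied to the 0.1 Hz-filtered
data (preserving the slow components the decoder needs).  Ocular
components are scored deterministically from their frontal topography and
low-frequency power; components scoring above threshold are removed in
descending order, capped at three per session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, filtfilt, firwin, iirnotch, resample_poly, welch
from scipy import stats

from .channels import CHANNELS, indices


@dataclass
class PreprocessConfig:
    """Parameters of the cleaning chain (frequencies in Hz, times in s)."""

    notch_hz: float = 50.0
    bandpass: tuple[float, float] = (0.1, 30.0)
    bandpass_transition_hz: float = 0.1
    ica_fit_highpass_hz: float = 1.0
    ocular_score_threshold: float = 0.85
    max_removed_components: int = 3
    baseline_window: tuple[float, float] = (-1.0, 0.0)
    epoch_window: tuple[float, float] = (-0.5, 6.5)
    out_rate_hz: float = 100.0
    bad_z_threshold: float = 5.0
    bad_corr_threshold: float = 0.2
    ica_seed: int = 0
    ica_max_iter: int = 800

    def __post_init__(self) -> None:
        lo, hi = self.bandpass
        if not 0 < lo < hi:
            raise ValueError("bandpass must satisfy 0 < low < high")
        if self.max_removed_components < 0:
            raise ValueError("max_removed_components must be >= 0")


@dataclass
class CleanEpoch:
    """One trial's cleaned, baseline-corrected EEG (channels x samples)."""

    eeg: np.ndarray
    trial_id: int
    bad_channel_log: list = field(default_factory=list)
    removed_component_count: int = 0
    rate_hz: float = 100.0


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _zero_phase_fir(data: np.ndarray, h: np.ndarray, passes: int = 2) -> np.ndarray:
    """Apply a symmetric odd-length FIR with zero net delay.

    The kernel is linear-phase, so each 'same'-mode convolution is already
    delay-free; two passes emulate forward-backward filtering (attenuation
    in dB doubles).  Edges are reflection-padded up to half the kernel.
    """
    n = data.shape[-1]
    edge = min(len(h) // 2, n - 1)
    out = data
    for _ in range(passes):
        padded = np.concatenate(
            [out[..., 1:edge + 1][..., ::-1], out, out[..., -edge - 1:-1][..., ::-1]],
            axis=-1,
        )
        out = fftconvolve(padded, h[np.newaxis, :] if data.ndim == 2 else h,
                          mode="same", axes=-1)[..., edge:edge + n]
    return out


def _fir_taps(fs: float, transition_hz: float, n_samples: int) -> int:
    """Hamming-window FIR length for a transition width, capped by data length."""
    taps = int(np.ceil(3.3 * fs / transition_hz))
    taps = min(taps, max(3, (n_samples // 2) * 2 - 1))
    return taps + 1 if taps % 2 == 0 else taps


def notch_filter(eeg: np.ndarray, fs: float, notch_hz: float = 50.0,
                 quality: float = 35.0) -> np.ndarray:
    """Zero-phase IIR notch at the line frequency."""
    if fs <= 2 * notch_hz:
        raise ValueError(f"sampling rate {fs} Hz too low for a {notch_hz} Hz notch")
    b, a = iirnotch(notch_hz, quality, fs=fs)
    return filtfilt(b, a, eeg, axis=-1)


def bandpass_zero_phase(eeg: np.ndarray, fs: float,
                        band: tuple[float, float] = (0.1, 30.0),
                        transition_hz: float = 0.1) -> np.ndarray:
    """Zero-phase windowed-sinc FIR band-pass (Hamming window)."""
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz is not below Nyquist ({fs / 2} Hz)")
    taps = _fir_taps(fs, transition_hz, eeg.shape[-1])
    h = firwin(taps, [lo, hi], pass_zero=False, window="hamming", fs=fs)
    return _zero_phase_fir(eeg, h)


def highpass_zero_phase(eeg: np.ndarray, fs: float, cutoff_hz: float,
                        transition_hz: float = 0.5) -> np.ndarray:
    """Zero-phase FIR high-pass (used for the ICA fitting copy)."""
    taps = _fir_taps(fs, transition_hz, eeg.shape[-1])
    h = firwin(taps, cutoff_hz, pass_zero=False, window="hamming", fs=fs)
    return _zero_phase_fir(eeg, h)


def lowpass_zero_phase(eeg: np.ndarray, fs: float, cutoff_hz: float,
                       transition_hz: float = 2.0) -> np.ndarray:
    """Zero-phase FIR low-pass."""
    taps = _fir_taps(fs, transition_hz, eeg.shape[-1])
    h = firwin(taps, cutoff_hz, pass_zero=True, window="hamming", fs=fs)
    return _zero_phase_fir(eeg, h)


# ---------------------------------------------------------------------------
# channel hygiene
# ---------------------------------------------------------------------------

def detect_bad_channels(eeg: np.ndarray, z_threshold: float = 5.0,
                        corr_threshold: float = 0.2) -> list[int]:
    """Automated stand-in for manual bad-channel inspection.

    Flags a channel when the robust z-score of its log-variance exceeds
    ``z_threshold`` (dead or saturated channels) or when its maximum
    absolute correlation with every other channel falls below
    ``corr_threshold`` (disconnected channels).  The MAD scale is floored
    at 0.5 natural-log units so physiological variance differences across
    the scalp are not flagged.
    """
    if eeg.shape[0] < 2:
        raise ValueError("need at least two channels")
    logv = np.log(eeg.var(axis=1) + 1e-30)
    med = np.median(logv)
    scale = max(1.4826 * np.median(np.abs(logv - med)), 0.5)
    z = (logv - med) / scale
    bad = set(np.flatnonzero(np.abs(z) > z_threshold).tolist())

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(eeg)
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)
    max_corr = np.abs(corr).max(axis=1)
    bad |= set(np.flatnonzero(max_corr < corr_threshold).tolist())
    return sorted(bad)


def interpolate_channels(eeg: np.ndarray, bad_list: list[int], fs: float,
                         ch_names: tuple[str, ...] = CHANNELS) -> np.ndarray:
    """Replace flagged channels by spherical-spline estimates.

    Uses the standard 10-10 head model; refuses when more than 25 % of
    channels are flagged (the spline becomes unreliable).
    """
    if not bad_list:
        return eeg
    n_ch = eeg.shape[0]
    if len(bad_list) > 0.25 * n_ch:
        raise ValueError(
            f"{len(bad_list)} of {n_ch} channels flagged; interpolation is "
            "unreliable beyond 25 %"
        )
    import mne

    info = mne.create_info(list(ch_names), sfreq=fs, ch_types="eeg")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    raw = mne.io.RawArray(eeg * 1e-6, info, verbose="error")
    raw.set_montage(montage, verbose="error")
    raw.info["bads"] = [ch_names[i] for i in bad_list]
    raw.interpolate_bads(reset_bads=True, verbose="error")
    return raw.get_data() * 1e6


def common_average_reference(eeg: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean across channels from every channel."""
    if eeg.shape[0] < 2:
        raise ValueError("CAR requires at least two channels")
    return eeg - eeg.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# ICA ocular-artifact removal
# ---------------------------------------------------------------------------

def _ocular_scores(mixing: np.ndarray, sources: np.ndarray, fs: float) -> np.ndarray:
    """Deterministic ocularity score per component in [0, 1].

    Geometric mean of three normalized factors: (a) eye-proximal
    topography — the component's largest absolute loading over the
    prefrontal electrodes (Fp1/Fp2) relative to its largest loading
    anywhere; (b) the fraction of source power below 4 Hz; and (c)
    transient sparsity — excess kurtosis of the source waveform scaled
    to saturate at 10 (blinks are brief, large deflections).  Genuine
    blink components drive all three factors towards 1; slow neural
    background matches (b) but not (a) and (c) together.
    """
    fp_idx = indices(("Fp1", "Fp2"))
    a = np.abs(mixing[fp_idx]).max(axis=0) / (np.abs(mixing).max(axis=0) + 1e-30)
    nperseg = min(sources.shape[1], int(4 * fs))
    freqs, psd = welch(sources, fs=fs, nperseg=nperseg, axis=1)
    total = psd.sum(axis=1) + 1e-30
    b = psd[:, freqs < 4.0].sum(axis=1) / total
    c = np.clip(stats.kurtosis(sources, axis=1) / 10.0, 0.0, 1.0)
    return np.cbrt(a * b * c)


def _pca_whiten(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demean and whiten to numerical rank; returns (whitener, z)."""
    xc = x - x.mean(axis=1, keepdims=True)
    cov = xc @ xc.T / xc.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > 1e-10 * evals[0]
    whitener = (evecs[:, keep] / np.sqrt(evals[keep])).T
    return whitener, whitener @ xc


def ica_remove_ocular(
    session_eeg: np.ndarray,
    fs: float,
    config: PreprocessConfig | None = None,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Estimate ICA on a 1 Hz high-passed copy and remove ocular components.

    The decomposition is extended infomax (the EEGLAB default family) on
    PCA-whitened data at the numerical rank; the resulting unmixing is
    applied to the *non*-high-passed signal, preserving sub-1 Hz
    information.  Components scoring at or above the ocular threshold
    are removed in descending score order, at most
    ``max_removed_components`` of them.  Returns
    ``(cleaned_eeg, removed_count, scores)``.
    """
    from mne.preprocessing import infomax

    config = config or PreprocessConfig()
    x_fit = highpass_zero_phase(session_eeg, fs, config.ica_fit_highpass_hz)
    whitener, z = _pca_whiten(x_fit)

    weights = None
    for attempt in range(2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = infomax(z.T, extended=True, max_iter=config.ica_max_iter,
                        rng=config.ica_seed + attempt, verbose="error")
        if np.all(np.isfinite(w)):
            weights = w
            break
    if weights is None:
        raise RuntimeError("ICA failed to converge after a seed retry")

    unmixing = weights @ whitener        # (n_comp, n_ch)
    mixing = np.linalg.pinv(unmixing)    # (n_ch, n_comp)
    demeaned = session_eeg - session_eeg.mean(axis=1, keepdims=True)
    sources = unmixing @ demeaned

    scores = _ocular_scores(mixing, sources, fs)
    candidates = np.flatnonzero(scores >= config.ocular_score_threshold)
    order = candidates[np.argsort(scores[candidates])[::-1]]
    selected = order[: config.max_removed_components]

    cleaned = session_eeg
    if selected.size:
        cleaned = session_eeg - mixing[:, selected] @ sources[selected]
    return cleaned, int(selected.size), scores


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def epoch_and_baseline(
    session_eeg: np.ndarray,
    triggers: list[dict],
    fs: float,
    config: PreprocessConfig | None = None,
    bad_channel_log: list | None = None,
    removed_component_count: int = 0,
) -> list[CleanEpoch]:
    """Cut trial epochs, subtract the pre-movement baseline, downsample.

    The per-channel mean over ``baseline_window`` (relative to movement
    onset, on the continuous data) is subtracted from the whole analysis
    epoch ``epoch_window``; the epoch is then rate-converted to
    ``out_rate_hz`` by polyphase resampling.
    """
    config = config or PreprocessConfig()
    b0, b1 = config.baseline_window
    e0, e1 = config.epoch_window
    n = session_eeg.shape[1]
    epochs = []
    for trig in triggers:
        m = trig["move_on"]
        bi0, bi1 = m + int(round(b0 * fs)), m + int(round(b1 * fs))
        ei0, ei1 = m + int(round(e0 * fs)), m + int(round(e1 * fs))
        if bi0 < 0 or ei0 < 0 or ei1 > n or bi1 > n:
            raise ValueError(
                f"trial {trig.get('trial_id', '?')}: baseline/epoch window "
                "exceeds the continuous recording"
            )
        baseline = session_eeg[:, bi0:bi1].mean(axis=1, keepdims=True)
        cut = session_eeg[:, ei0:ei1] - baseline
        if config.out_rate_hz != fs:
            up, down = _rate_fraction(config.out_rate_hz, fs)
            cut = resample_poly(cut, up, down, axis=1)
        epochs.append(CleanEpoch(
            eeg=cut,
            trial_id=trig.get("trial_id", 0),
            bad_channel_log=list(bad_channel_log or []),
            removed_component_count=removed_component_count,
            rate_hz=config.out_rate_hz,
        ))
    return epochs


def _rate_fraction(target: float, fs: float) -> tuple[int, int]:
    up, down = int(round(target)), int(round(fs))
    g = np.gcd(up, down)
    return up // g, down // g


# ---------------------------------------------------------------------------
# session pipeline
# ---------------------------------------------------------------------------

def clean_session_continuous(
    session_eeg: np.ndarray,
    fs: float,
    config: PreprocessConfig | None = None,
) -> tuple[np.ndarray, list[int], int, np.ndarray]:
    """Run the continuous-data part of the chain (everything but epoching).

    Returns ``(cleaned, bad_channels, removed_count, scores)``.
    """
    config = config or PreprocessConfig()
    x = notch_filter(session_eeg, fs, config.notch_hz)
    x = bandpass_zero_phase(x, fs, config.bandpass, config.bandpass_transition_hz)
    bad = detect_bad_channels(x, config.bad_z_threshold, config.bad_corr_threshold)
    x = interpolate_channels(x, bad, fs)
    x = common_average_reference(x)
    x, removed, scores = ica_remove_ocular(x, fs, config)
    return x, bad, removed, scores


def preprocess_session(
    session_eeg: np.ndarray,
    triggers: list[dict],
    fs: float,
    config: PreprocessConfig | None = None,
) -> tuple[list[CleanEpoch], dict]:
    """Run the full cleaning chain on one session's continuous EEG.

    Returns the per-trial cleaned epochs and a JSON-serializable log of
    what was done (bad channels, ICA component scores, filter settings).
    """
    config = config or PreprocessConfig()
    x, bad, removed, scores = clean_session_continuous(session_eeg, fs, config)
    epochs = epoch_and_baseline(x, triggers, fs, config,
                                bad_channel_log=bad,
                                removed_component_count=removed)
    log = {
        "bad_channels": [CHANNELS[i] for i in bad],
        "removed_components": removed,
        "component_scores": np.round(scores, 4).tolist(),
        "notch_hz": config.notch_hz,
        "bandpass": list(config.bandpass),
        "out_rate_hz": config.out_rate_hz,
    }
    return epochs, log
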
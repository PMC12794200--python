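"""Windowed dataset construction: standardization, sliding windows, splits.

Cleaned 32 x 700 epochs are standardized per channel (population SD),
cut into 1-s windows stepped by 0.05 s (121 windows per 7-s trial), and
labeled with the polar angle at each window's centre (50th) sample.
Trials are shuffled once, every k-th trial enters the held-out test set
(systematic sampling), and the remainder is partitioned into 10 equal
cross-validation folds.  Split assignment is at trial level, so no
trial's windows ever straddle the test/train boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import AngleEpoch
from .preprocessing import CleanEpoch

TEST_FOLD = -1  # split_assignment value marking test trials


@dataclass
class ChannelStats:
    """Per-channel mean and population SD used for standardization (uV)."""

    mean_per_channel: np.ndarray
    sd_per_channel: np.ndarray


@dataclass
class WindowDataset:
    """Standardized EEG windows with centre-sample angle labels.

    ``windows``: (n_windows, n_channels, window_len); ``labels``: rad in
    [0, 2pi); ``trial_ids``: provenance per window; ``split_assignment``:
    per-trial mapping to the test set (:data:`TEST_FOLD`) or fold 1..n.
    """

    windows: np.ndarray
    labels: np.ndarray
    trial_ids: np.ndarray
    split_assignment: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    def window_fold(self) -> np.ndarray:
        """Fold id per window, from the trial-level assignment."""
        return np.array([self.split_assignment[t] for t in self.trial_ids])

    def subset(self, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.windows[mask], self.labels[mask], self.trial_ids[mask]


def standardize(
    epochs: np.ndarray,
    stats: ChannelStats | None = None,
) -> tuple[np.ndarray, ChannelStats]:
    """Standardize each channel to zero mean, unit population SD.

    ``epochs`` is (n_trials, n_channels, n_samples); statistics are pooled
    over all trials and samples of the scope unless precomputed ``stats``
    are supplied (e.g. train-only statistics for leakage-strict runs).
    """
    epochs = np.asarray(epochs, dtype=float)
    if stats is None:
        mean = epochs.mean(axis=(0, 2))
        sd = epochs.std(axis=(0, 2))  # population SD (ddof=0)
        stats = ChannelStats(mean_per_channel=mean, sd_per_channel=sd)
    zero = np.flatnonzero(stats.sd_per_channel <= 0)
    if zero.size:
        raise ValueError(f"zero-variance channel(s) {zero.tolist()} cannot be standardized")
    out = (epochs - stats.mean_per_channel[None, :, None]) / stats.sd_per_channel[None, :, None]
    return out, stats


def window_count(n_samples: int, win: int = 100, step: int = 5) -> int:
    """Number of complete sliding windows: floor((N - win)/step) + 1."""
    if n_samples < win:
        raise ValueError(f"epoch of {n_samples} samples is shorter than one window")
    return (n_samples - win) // step + 1


def slide_windows(
    epoch: np.ndarray,
    angle: AngleEpoch | np.ndarray,
    win_s: float = 1.0,
    step_s: float = 0.05,
    rate_hz: float = 100.0,
    label_index: int = 49,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut one trial into windows and take centre-sample angle labels.

    The label of each window is the angle at its 50th sample (zero-based
    index ``label_index`` = 49).  Incomplete terminal segments are
    discarded.  Returns ``(windows, labels)`` with windows shaped
    (n_windows, n_channels, win).
    """
    theta = angle.theta if isinstance(angle, AngleEpoch) else np.asarray(angle)
    epoch = np.asarray(epoch)
    if epoch.shape[-1] != theta.shape[-1]:
        raise ValueError("epoch and angle series must have equal length")
    win = int(round(win_s * rate_hz))
    step = int(round(step_s * rate_hz))
    n = window_count(epoch.shape[-1], win, step)
    starts = np.arange(n) * step
    windows = np.stack([epoch[:, s : s + win] for s in starts])
    labels = theta[starts + label_index]
    return windows, labels


def split_dataset(
    trial_ids,
    shuffle_seed: int = 0,
    n_test: int = 20,
    n_folds: int = 10,
) -> dict:
    """Shuffle trials, systematically sample a test set, fold the rest.

    After a seeded shuffle, every k-th trial (k = count / n_test, phase 0)
    enters the test set; the remaining trials are partitioned in shuffled
    order into ``n_folds`` equal folds (1..n_folds).  Returns a mapping
    trial_id -> fold, with :data:`TEST_FOLD` marking test trials.
    """
    trial_ids = list(trial_ids)
    count = len(trial_ids)
    if count < n_test + n_folds:
        raise ValueError(f"{count} trials cannot supply {n_test} test trials "
                         f"and {n_folds} folds")
    if count % n_test != 0:
        raise ValueError(
            f"trial count {count} is not a multiple of n_test={n_test}; "
            "systematic sampling needs an integer stride — adjust n_test"
        )
    k = count // n_test
    remaining = count - n_test
    if remaining % n_folds != 0:
        raise ValueError(
            f"{remaining} non-test trials do not divide into {n_folds} equal "
            "folds — adjust n_test or n_folds"
        )
    rng = np.random.default_rng(shuffle_seed)
    order = list(np.array(trial_ids)[rng.permutation(count)])
    test = set(order[::k])
    rest = [t for t in order if t not in test]
    per_fold = remaining // n_folds
    assignment: dict = {int(t): TEST_FOLD for t in test}
    for f in range(n_folds):
        for t in rest[f * per_fold : (f + 1) * per_fold]:
            assignment[int(t)] = f + 1
    return assignment


def build_dataset(
    epochs: list[CleanEpoch],
    angles: list[AngleEpoch],
    shuffle_seed: int = 0,
    n_test: int = 20,
    n_folds: int = 10,
    train_only_stats: bool = False,
) -> WindowDataset:
    """Assemble the full windowed dataset for one subject.

    Standardization statistics are pooled over all trials by default
    (matching the construction order standardize-then-split); with
    ``train_only_stats`` they are computed from non-test trials only,
    avoiding the mild test-set leakage of the default.
    """
    if len(epochs) != len(angles):
        raise ValueError("epoch and angle lists must align")
    order = {a.trial_id: a for a in angles}
    eeg = np.stack([e.eeg for e in epochs])
    ids = [e.trial_id for e in epochs]
    assignment = split_dataset(ids, shuffle_seed, n_test, n_folds)

    if train_only_stats:
        train_mask = np.array([assignment[t] != TEST_FOLD for t in ids])
        _, stats = standardize(eeg[train_mask])
        eeg, _ = standardize(eeg, stats)
    else:
        eeg, stats = standardize(eeg)

    all_windows, all_labels, all_ids = [], [], []
    for i, e in enumerate(epochs):
        w, lab = slide_windows(eeg[i], order[e.trial_id])
        all_windows.append(w)
        all_labels.append(lab)
        all_ids.append(np.full(len(lab), e.trial_id))
    ds = WindowDataset(
        windows=np.concatenate(all_windows).astype(np.float32),
        labels=np.concatenate(all_labels),
        trial_ids=np.concatenate(all_ids),
        split_assignment=assignment,
    )
    _assert_no_leakage(ds)
    return ds


def _assert_no_leakage(ds: WindowDataset) -> None:
    """Guard: no trial contributes windows to both test and training."""
    folds = ds.window_fold()
    test_trials = set(ds.trial_ids[folds == TEST_FOLD])
    train_trials = set(ds.trial_ids[folds != TEST_FOLD])
    overlap = test_trials & train_trials
    if overlap:
        raise AssertionError(f"trials {sorted(overlap)} straddle the test split")
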
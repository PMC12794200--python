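"""Small helpers shared by test modules."""

from __future__ import annotations

import numpy as np

from polardecode import TrainConfig, WindowDataset, train_fold
from polardecode.dataset import split_dataset


class SpyModel:
    """Minimal model stub that records the training batches it receives."""

    def __init__(self):
        self.batch_sizes: list[int] = []

    def forward(self, x, training=False):
        if training:
            self.batch_sizes.append(len(x))
        return np.zeros((len(x), 1), dtype=np.float32)

    def backward(self, grad):
        return grad

    def params(self):
        return []

    def zero_grad(self):
        pass

    def get_weights(self):
        return []

    def set_weights(self, weights):
        pass


def spy_train_batches(n_trials: int, n_test: int, n_folds: int,
                      seed: int = 0) -> list[int]:
    """Batch sizes produced by one training epoch on a dummy dataset."""
    rng = np.random.default_rng(seed)
    windows = rng.standard_normal((n_trials * 121, 1, 4)).astype(np.float32)
    labels = rng.uniform(0, 2 * np.pi, n_trials * 121)
    trial_ids = np.repeat(np.arange(n_trials), 121)
    assignment = split_dataset(range(n_trials), shuffle_seed=seed,
                               n_test=n_test, n_folds=n_folds)
    ds = WindowDataset(windows=windows, labels=labels, trial_ids=trial_ids,
                       split_assignment=assignment)
    spy = SpyModel()
    train_fold(spy, ds, 1, TrainConfig(max_epochs=1, early_stop_patience=1))
    return spy.batch_sizes
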
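"""Fold training mechanics, metrics and the decoded-vs-chance comparison."""

import numpy as np
import pytest

from polardecode import (TEST_FOLD, TrainConfig, WindowDataset, compare_to_chance,
                         evaluate, permuted_labels, train_fold)
from polardecode.training import EvalResult, FoldResult


class _SpyModel:
    """Minimal model stub recording the batches it is asked to fit."""

    def __init__(self):
        self.batch_sizes = []
        self.batch_trials = []

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


def _synthetic_window_dataset(n_trials=200, n_test=20, n_folds=10, seed=0):
    rng = np.random.default_rng(seed)
    windows = rng.standard_normal((n_trials * 121, 1, 4)).astype(np.float32)
    labels = rng.uniform(0, 2 * np.pi, n_trials * 121)
    trial_ids = np.repeat(np.arange(n_trials), 121)
    from polardecode.dataset import split_dataset

    assignment = split_dataset(range(n_trials), shuffle_seed=seed,
                               n_test=n_test, n_folds=n_folds)
    return WindowDataset(windows=windows, labels=labels, trial_ids=trial_ids,
                         split_assignment=assignment)


class TestBatching:
    def test_batches_are_nine_whole_trials_of_1089_windows(self):
        ds = _synthetic_window_dataset()
        spy = _SpyModel()
        config = TrainConfig(max_epochs=1, early_stop_patience=1)
        train_fold(spy, ds, 1, config)
        # 162 training trials -> 18 batches of exactly 9 x 121 windows
        assert len(spy.batch_sizes) == 18
        assert set(spy.batch_sizes) == {1089}

    def test_partial_final_batch_allowed(self):
        ds = _synthetic_window_dataset(n_trials=40, n_test=4, n_folds=4)
        spy = _SpyModel()
        train_fold(spy, ds, 1, TrainConfig(max_epochs=1, early_stop_patience=1))
        # 27 training trials -> 9 + 9 + 9 per epoch
        assert spy.batch_sizes == [1089, 1089, 1089]

    def test_unknown_fold_rejected(self):
        ds = _synthetic_window_dataset(n_trials=40, n_test=4, n_folds=4)
        with pytest.raises(ValueError, match="fold"):
            train_fold(_SpyModel(), ds, 99, TrainConfig(max_epochs=1))


class TestEarlyStopping:
    def test_plateau_stops_after_patience_epochs(self):
        # zero learning rate -> validation loss can never improve after
        # the first epoch, so training stops at exactly 1 + patience
        ds = _synthetic_window_dataset(n_trials=20, n_test=2, n_folds=3)
        from polardecode.decoders import DecoderSpec

        config = TrainConfig(learning_rate=0.0, max_epochs=50,
                             early_stop_patience=4, seed=0)
        spec = DecoderSpec(family="eegnet", input_shape=(1, 4), seed=0)
        # a tiny stand-in net with the right interface is enough
        from polardecode import nn

        model = nn.Sequential([nn.Flatten(), nn.Dense(4, 1)], seed=0)
        trained = train_fold(model, ds, 1, config)
        assert trained.stopped_epoch == 1 + 4
        assert trained.best_epoch == 1

    def test_training_is_deterministic(self):
        ds = _synthetic_window_dataset(n_trials=20, n_test=2, n_folds=3)
        from polardecode import nn

        def run():
            model = nn.Sequential([nn.Flatten(), nn.Dense(4, 1)], seed=0)
            cfg = TrainConfig(max_epochs=3, early_stop_patience=3, seed=7)
            return train_fold(model, ds, 1, cfg).training_history

        assert run() == run()


class TestEvaluate:
    class _Identity:
        def __init__(self, values):
            self.values = np.asarray(values, dtype=np.float32)

        def forward(self, x, training=False):
            return self.values[: len(x)].reshape(-1, 1)

    def test_perfect_predictions(self, rng):
        y = rng.uniform(0, 6.28, 200)
        res = evaluate(self._Identity(y), np.zeros((200, 1)), y)
        assert res.mse == pytest.approx(0.0, abs=1e-10)
        assert res.mae == pytest.approx(0.0, abs=1e-6)
        assert res.cc == pytest.approx(1.0, abs=1e-6)
        assert res.r2 == pytest.approx(1.0, abs=1e-6)

    def test_constant_shift(self, rng):
        y = rng.uniform(0, 6.28, 500)
        res = evaluate(self._Identity(y + 0.5), np.zeros((500, 1)), y)
        assert res.mse == pytest.approx(0.25, abs=1e-5)
        assert res.mae == pytest.approx(0.5, abs=1e-5)
        assert res.cc == pytest.approx(1.0, abs=1e-5)

    def test_independent_uniform_pairs_monte_carlo(self, rng):
        """E[(X-Y)^2] = 2 Var = (2 pi)^2 / 6 for independent uniforms."""
        n = 100_000
        y = rng.uniform(0, 2 * np.pi, n)
        pred = rng.uniform(0, 2 * np.pi, n)
        res = evaluate(self._Identity(pred), np.zeros((n, 1)), y)
        assert res.cc == pytest.approx(0.0, abs=0.02)
        assert res.mse == pytest.approx((2 * np.pi) ** 2 / 6, rel=0.02)

    def test_degenerate_constant_predictions_flagged(self, rng):
        y = rng.uniform(0, 6.28, 100)
        res = evaluate(self._Identity(np.full(100, 3.0)), np.zeros((100, 1)), y)
        assert res.cc == 0.0
        assert res.cc_degenerate

    def test_jensen_inequality_on_random_evaluations(self, rng):
        for _ in range(20):
            y = rng.uniform(0, 6.28, 50)
            pred = y + rng.normal(0, rng.uniform(0.1, 2.0), 50)
            res = evaluate(self._Identity(pred), np.zeros((50, 1)), y)
            assert res.mae ** 2 <= res.mse + 1e-12


class TestPermutation:
    def test_train_labels_permuted_test_untouched(self):
        ds = _synthetic_window_dataset(n_trials=40, n_test=4, n_folds=4)
        permuted = permuted_labels(ds, permutation_seed=3)
        folds = ds.window_fold()
        test = folds == TEST_FOLD
        assert np.array_equal(permuted[test], ds.labels[test])
        assert not np.array_equal(permuted[~test], ds.labels[~test])
        assert np.allclose(np.sort(permuted[~test]), np.sort(ds.labels[~test]))


class TestCompareToChance:
    def _result(self, ccs, mses, maes):
        return EvalResult(per_fold=[
            FoldResult(mse=m, mae=a, cc=c, r2=0.0)
            for c, m, a in zip(ccs, mses, maes)
        ])

    def test_identical_inputs_are_not_significant(self, rng):
        vals = rng.uniform(0.5, 1.0, 10)
        a = self._result(vals, vals, vals)
        b = self._result(vals, vals, vals)
        out = compare_to_chance(a, b)
        for metric in ("mse", "mae", "cc"):
            assert out[metric]["p"] > 0.9

    def test_separated_distributions_are_significant(self, rng):
        decoded = self._result(rng.normal(0.9, 0.05, 10),
                               rng.normal(1.0, 0.1, 10),
                               rng.normal(0.6, 0.05, 10))
        chance = self._result(rng.normal(0.0, 0.1, 10),
                              rng.normal(6.6, 0.3, 10),
                              rng.normal(2.0, 0.1, 10))
        out = compare_to_chance(decoded, chance)
        for metric in ("mse", "mae", "cc"):
            assert out[metric]["p"] < 0.001
            assert out[metric]["p_permutation"] < 0.01
            assert set(out[metric]) == {"F", "df", "p", "p_permutation"}

    def test_mismatched_or_tiny_fold_counts_rejected(self, rng):
        a = self._result([0.5], [1.0], [0.6])
        b = self._result([0.1, 0.2], [2.0, 2.1], [1.0, 1.1])
        with pytest.raises(ValueError):
            compare_to_chance(a, b)
        with pytest.raises(ValueError):
            compare_to_chance(a, self._result([0.1], [2.0], [1.0]))
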
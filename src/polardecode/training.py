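"""Fold-wise training, test-set evaluation and permutation chance levels.

Each cross-validation fold trains a fresh decoder on the other nine
folds' windows (mini-batches of nine whole trials = 1089 windows under
the default windowing), validates on the held-out fold with early
stopping, and is evaluated on the fixed test set.  The chance level
repeats the identical procedure with training/validation labels randomly
permuted at window level, leaving test labels intact.  Decoded and
chance metrics are compared fold-wise by one-way ANOVA plus a paired
sign-flip permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import nn
from .dataset import TEST_FOLD, WindowDataset
from .decoders import DecoderSpec, build_decoder


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the study protocol)."""

    learning_rate: float = 0.002
    batch_trials: int = 9          # 9 trials x 121 windows = 1089-window batches
    max_epochs: int = 1000
    early_stop_patience: int = 50
    min_delta: float = 1e-4        # improvement below this does not reset patience
    restore_best: bool = True
    seed: int = 0
    eval_batch: int = 4096

    def __post_init__(self) -> None:
        if self.batch_trials < 1 or self.max_epochs < 1:
            raise ValueError("batch_trials and max_epochs must be positive")


@dataclass
class TrainedDecoder:
    """A fitted model with its training history."""

    spec: DecoderSpec
    model: nn.Sequential
    training_history: list = field(default_factory=list)  # (train, val) loss per epoch
    stopped_epoch: int = 0


@dataclass
class FoldResult:
    """Test-set metrics of one fold's decoder."""

    mse: float
    mae: float
    cc: float
    r2: float
    cc_degenerate: bool = False
    predictions: np.ndarray | None = None
    history: list | None = None  # (train, validation) loss per epoch


@dataclass
class EvalResult:
    """Per-fold metrics plus aggregate mean +/- SD."""

    per_fold: list[FoldResult]
    labels: np.ndarray | None = None
    trial_ids: np.ndarray | None = None

    def metric(self, name: str) -> np.ndarray:
        return np.array([getattr(f, name) for f in self.per_fold])

    def aggregate(self) -> dict:
        out = {}
        for name in ("mse", "mae", "cc", "r2"):
            vals = self.metric(name)
            out[name] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
        return out

    def mean_prediction(self) -> tuple[np.ndarray, np.ndarray]:
        """Across-fold mean predicted trace and its 95% t-interval half-width."""
        preds = np.stack([f.predictions for f in self.per_fold])
        mean = preds.mean(axis=0)
        n = preds.shape[0]
        if n > 1:
            sem = preds.std(axis=0, ddof=1) / np.sqrt(n)
            half = sem * stats.t.ppf(0.975, n - 1)
        else:
            half = np.zeros_like(mean)
        return mean, half


def predict(model: nn.Sequential, windows: np.ndarray, batch: int = 4096) -> np.ndarray:
    """Inference-mode forward pass in memory-bounded batches."""
    out = [model.forward(windows[i:i + batch], training=False).reshape(-1)
           for i in range(0, len(windows), batch)]
    return np.concatenate(out) if out else np.empty(0)


def _fold_windows(dataset: WindowDataset, folds: np.ndarray, labels: np.ndarray,
                  which) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mask = np.isin(folds, np.atleast_1d(which))
    return dataset.windows[mask], labels[mask], dataset.trial_ids[mask]


def train_fold(
    model_or_spec,
    dataset: WindowDataset,
    fold_k: int,
    config: TrainConfig,
    labels: np.ndarray | None = None,
) -> TrainedDecoder:
    """Train one fold's decoder with early stopping on validation loss.

    ``labels`` overrides the dataset's labels (used for permutation
    runs); test-fold windows are never touched.  Mini-batches are drawn
    as ``batch_trials`` whole trials in a seeded, reshuffled order each
    epoch; a smaller final batch is allowed when the trial count does not
    divide evenly.
    """
    folds = dataset.window_fold()
    all_folds = sorted(set(folds) - {TEST_FOLD})
    if fold_k not in all_folds:
        raise ValueError(f"fold {fold_k} not present (have {all_folds})")
    labels = dataset.labels if labels is None else labels

    if isinstance(model_or_spec, DecoderSpec):
        spec = model_or_spec
        model = build_decoder(spec)
    else:
        model = model_or_spec
        spec = getattr(model, "spec", DecoderSpec())

    train_folds = [f for f in all_folds if f != fold_k]
    x_val, y_val, _ = _fold_windows(dataset, folds, labels, fold_k)
    if x_val.size == 0:
        raise ValueError(f"validation fold {fold_k} is empty")
    train_mask = np.isin(folds, train_folds)
    train_trials = np.unique(dataset.trial_ids[train_mask])

    # leakage guard: training/validation trials must never meet the test set
    test_trials = set(dataset.trial_ids[folds == TEST_FOLD])
    assert not (set(train_trials) & test_trials), "train/test trial overlap"

    trial_index = {
        t: np.flatnonzero(dataset.trial_ids == t) for t in train_trials
    }
    rng = np.random.default_rng(config.seed)
    loss_fn = nn.MSELoss()
    optimizer = nn.Adam(model.params(), lr=config.learning_rate)

    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    history: list[tuple[float, float]] = []
    wait = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(train_trials)
        epoch_losses = []
        for start in range(0, len(order), config.batch_trials):
            chunk = order[start:start + config.batch_trials]
            idx = np.concatenate([trial_index[t] for t in chunk])
            xb = dataset.windows[idx]
            yb = labels[idx]
            model.zero_grad()
            pred = model.forward(xb, training=True)
            loss = loss_fn.forward(pred, yb)
            model.backward(loss_fn.backward())
            optimizer.step()
            epoch_losses.append(loss)
        val_pred = predict(model, x_val, config.eval_batch)
        val_loss = float(np.mean((val_pred - y_val) ** 2))
        history.append((float(np.mean(epoch_losses)), val_loss))
        if val_loss < best_val - config.min_delta:
            best_val = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
            wait = 0
        else:
            if val_loss < best_val:  # still track the best weights
                best_val = val_loss
                best_weights = model.get_weights()
                best_epoch = epoch
            wait += 1
            if wait >= config.early_stop_patience:
                break
    if config.restore_best:
        model.set_weights(best_weights)
    trained = TrainedDecoder(spec=spec, model=model, training_history=history,
                             stopped_epoch=len(history))
    trained.best_epoch = best_epoch
    return trained


def evaluate(model: nn.Sequential, windows: np.ndarray, labels: np.ndarray,
             eval_batch: int = 4096) -> FoldResult:
    """Pooled test-window metrics: MSE, MAE, Pearson CC and R^2.

    Constant (degenerate) predictions get CC = 0 with a flag rather than
    NaN — permuted-label models can collapse to the mean.
    """
    pred = predict(model, windows, eval_batch)
    labels = np.asarray(labels, dtype=float)
    err = pred - labels
    mse = float(np.mean(err ** 2))
    mae = float(np.mean(np.abs(err)))
    degenerate = bool(np.std(pred) < 1e-12 or np.std(labels) < 1e-12)
    cc = 0.0 if degenerate else float(np.corrcoef(pred, labels)[0, 1])
    ss_tot = float(np.sum((labels - labels.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return FoldResult(mse=mse, mae=mae, cc=cc, r2=r2, cc_degenerate=degenerate,
                      predictions=pred)


def cross_validate(
    spec: DecoderSpec,
    dataset: WindowDataset,
    config: TrainConfig,
    labels: np.ndarray | None = None,
) -> EvalResult:
    """Train every fold's decoder and evaluate each on the fixed test set."""
    folds = dataset.window_fold()
    fold_ids = sorted(set(folds) - {TEST_FOLD})
    x_test, y_test, t_test = _fold_windows(dataset, folds, dataset.labels, TEST_FOLD)
    results = []
    for k in fold_ids:
        fold_spec = DecoderSpec(**{**spec.__dict__,
                                   "seed": spec.seed + 1000 * k,
                                   "first_layer_filters": spec.first_layer_filters})
        fold_config = TrainConfig(**{**config.__dict__, "seed": config.seed + k})
        try:
            trained = train_fold(fold_spec, dataset, k, fold_config, labels=labels)
        except Exception as err:
            raise RuntimeError(f"cross-validation failed at fold {k}: {err}") from err
        fold_result = evaluate(trained.model, x_test, y_test, config.eval_batch)
        fold_result.history = trained.training_history
        results.append(fold_result)
    return EvalResult(per_fold=results, labels=y_test, trial_ids=t_test)


def permuted_labels(dataset: WindowDataset, permutation_seed: int) -> np.ndarray:
    """Labels with the train+validation entries permuted, test intact."""
    folds = dataset.window_fold()
    mask = folds != TEST_FOLD
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        raise ValueError("nothing to permute")
    rng = np.random.default_rng(permutation_seed)
    labels = dataset.labels.copy()
    for _ in range(100):
        perm = rng.permutation(idx.size)
        if not np.array_equal(perm, np.arange(idx.size)):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not draw a non-identity permutation")
    labels[idx] = labels[idx[perm]]
    return labels


def chance_level(
    spec: DecoderSpec,
    dataset: WindowDataset,
    config: TrainConfig,
    permutation_seed: int = 0,
) -> EvalResult:
    """Chance-level baseline: identical protocol on permuted labels.

    One fresh window-level permutation of the train+validation labels is
    drawn per fold; evaluation uses the intact test labels.
    """
    folds = dataset.window_fold()
    fold_ids = sorted(set(folds) - {TEST_FOLD})
    x_test, y_test, t_test = _fold_windows(dataset, folds, dataset.labels, TEST_FOLD)
    results = []
    for i, k in enumerate(fold_ids):
        labels = permuted_labels(dataset, permutation_seed + 7919 * i)
        fold_spec = DecoderSpec(**{**spec.__dict__, "seed": spec.seed + 1000 * k})
        fold_config = TrainConfig(**{**config.__dict__, "seed": config.seed + k})
        trained = train_fold(fold_spec, dataset, k, fold_config, labels=labels)
        results.append(evaluate(trained.model, x_test, y_test, config.eval_batch))
    return EvalResult(per_fold=results, labels=y_test, trial_ids=t_test)


def compare_to_chance(decoded: EvalResult, chance: EvalResult,
                      n_permutations: int = 10000, seed: int = 0) -> dict:
    """Fold-wise decoded-vs-chance comparison per metric.

    One-way fixed-effects ANOVA (folds as observations) plus a paired
    sign-flip permutation p-value as a distribution-free companion.
    Returns ``{metric: {F, df, p, p_permutation}}``.
    """
    if len(decoded.per_fold) != len(chance.per_fold):
        raise ValueError("fold counts differ")
    n = len(decoded.per_fold)
    if n < 2:
        raise ValueError("need at least two folds")
    rng = np.random.default_rng(seed)
    out = {}
    for name in ("mse", "mae", "cc"):
        a = decoded.metric(name)
        b = chance.metric(name)
        f_stat, p = stats.f_oneway(a, b)
        diffs = a - b
        observed = abs(diffs.mean())
        if n <= 14:
            signs = np.array(np.meshgrid(*[[1, -1]] * n)).T.reshape(-1, n)
        else:
            signs = rng.choice([1, -1], size=(n_permutations, n))
        null = np.abs((signs * diffs).mean(axis=1))
        p_perm = float((null >= observed - 1e-15).mean())
        out[name] = {"F": float(f_stat), "df": (1, 2 * n - 2), "p": float(p),
                     "p_permutation": p_perm}
    return out
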
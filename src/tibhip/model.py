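"""LSTM sequence labelling of per-minute acceleration into in-bed / out-of-bed.

A stacked uni- or bidirectional LSTM maps a normalized per-minute tri-axial
series to a per-minute in-bed probability; minutes with probability >= 0.5 are
labelled in bed. Training minimizes per-minute binary cross-entropy with Adam
over augmented crops (see :mod:`tibhip.augment`); the hyperparameter grid spans
1/2/4 layers and 1–128 cells per layer, searched by subject-level k-fold
cross-validation, and the selected model is the sparsest one within one
standard error of the best mean accuracy.

Normalization provenance is enforced end to end: a trained model remembers the
hash of the statistics its inputs were standardized with, and refuses to
predict on a series normalized with anything else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._lstm import LSTMNet
from .augment import AugmentationConfig, AugmentedSample, augment_batch
from .io import MinuteSeries
from .preprocess import apply_normalizer, fit_normalizer

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "CVResult",
    "GRID_LAYERS",
    "GRID_CELLS",
    "DegenerateLabelsError",
    "IncompatibleNormalizationError",
    "ConfigurationError",
    "train",
    "predict",
    "cross_validate",
    "select_model",
    "save_model",
    "load_model",
]

GRID_LAYERS = (1, 2, 4)
GRID_CELLS = (1, 2, 4, 8, 16, 32, 64, 128)


class DegenerateLabelsError(ValueError):
    """The training labels contain a single class."""


class IncompatibleNormalizationError(ValueError):
    """The series was normalized with different statistics than the model."""


class ConfigurationError(ValueError):
    """Invalid training/CV configuration."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training controls.

    The architecture grid matches the hyperparameter search space; training
    controls default to Adam at 1e-3 with small batches and early stopping on
    the training-loss plateau.
    """

    bidirectional: bool = True
    n_layers: int = 2
    cells_per_layer: int = 16
    input_dim: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 3
    early_stop_patience: int = 2
    early_stop_min_delta: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.n_layers not in GRID_LAYERS:
            raise ConfigurationError(f"n_layers must be one of {GRID_LAYERS}")
        if self.cells_per_layer not in GRID_CELLS:
            raise ConfigurationError(f"cells_per_layer must be one of {GRID_CELLS}")
        if self.input_dim != 3:
            raise ConfigurationError("input_dim must be 3 (tri-axial)")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("max_epochs and batch_size must be >= 1")

    @property
    def n_parameters(self) -> int:
        """Analytic trainable-parameter count for this architecture."""
        n_dir = 2 if self.bidirectional else 1
        h = self.cells_per_layer
        total = 0
        d_in = self.input_dim
        for _ in range(self.n_layers):
            total += n_dir * 4 * h * (d_in + h + 1)
            d_in = h * n_dir
        total += d_in + 1  # logistic read-out
        return total


@dataclass
class TrainedModel:
    """A trained network plus everything needed to apply it reproducibly."""

    config: ModelConfig
    weights: dict[str, np.ndarray]
    norm_stats_ref: str | None
    training_log: list[dict] = field(default_factory=list)

    def network(self) -> LSTMNet:
        net = LSTMNet(self.config.input_dim, self.config.cells_per_layer,
                      self.config.n_layers, self.config.bidirectional,
                      seed=self.config.seed)
        net.load_state_dict(self.weights)
        return net


@dataclass(frozen=True)
class CVResult:
    """Cross-validation outcome for one grid cell."""

    config: ModelConfig
    fold_accuracies: tuple[float, ...]
    fold_assignments: tuple[tuple[int, ...], ...]  # validation subjects per fold
    norm_hashes: tuple[str, ...]  # per-fold training-normalizer hashes

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def se_accuracy(self) -> float:
        accs = np.asarray(self.fold_accuracies)
        if accs.size < 2:
            return 0.0
        return float(accs.std(ddof=1) / np.sqrt(accs.size))


# ---------------------------------------------------------------------------
# batching helpers


def _pad_batch(samples: list[AugmentedSample]):
    lengths = np.array([s.values.shape[0] for s in samples])
    T = int(lengths.max())
    B = len(samples)
    x = np.zeros((T, B, 3))
    y = np.zeros((T, B))
    mask = np.zeros((T, B))
    for b, s in enumerate(samples):
        L = lengths[b]
        x[:L, b] = s.values
        y[:L, b] = s.labels
        mask[:L, b] = 1.0
    return x, y, mask, lengths


def _check_training_inputs(samples: list[MinuteSeries]) -> None:
    if len(samples) < 2:
        raise ConfigurationError("need at least 2 training subjects")
    refs = set()
    classes = set()
    for s in samples:
        if s.labels is None:
            raise ConfigurationError("every training series must carry labels")
        if not s.normalized:
            raise ConfigurationError("training series must be normalized")
        refs.add(s.norm_ref)
        classes.update(np.unique(s.labels).tolist())
    if len(refs) != 1:
        raise IncompatibleNormalizationError(
            "all training series must share one NormalizationStats"
        )
    if len(classes) < 2:
        raise DegenerateLabelsError(
            "training labels contain a single class; nothing to discriminate"
        )


def train(samples: list[MinuteSeries], config: ModelConfig,
          aug_config: AugmentationConfig | None = None) -> TrainedModel:
    """Train an LSTM on normalized, labelled minute series.

    Each epoch draws fresh augmented crops from every source sequence,
    shuffles them into length-sorted mini-batches (to limit padding) and takes
    one Adam step per batch. Training stops when the epoch loss has not
    improved by ``early_stop_min_delta`` for ``early_stop_patience`` epochs,
    or at ``max_epochs``. Deterministic for a fixed config seed.
    """
    if aug_config is None:
        aug_config = AugmentationConfig()
    _check_training_inputs(samples)
    rng = np.random.default_rng(config.seed)
    net = LSTMNet(config.input_dim, config.cells_per_layer, config.n_layers,
                  config.bidirectional, seed=config.seed)
    log: list[dict] = []
    best_loss = np.inf
    stall = 0
    for epoch in range(config.max_epochs):
        crops = augment_batch(samples, aug_config, rng)
        order = rng.permutation(len(crops))
        crops = [crops[i] for i in order]
        crops.sort(key=lambda s: s.values.shape[0])
        batches = [crops[i:i + config.batch_size]
                   for i in range(0, len(crops), config.batch_size)]
        batch_order = rng.permutation(len(batches))
        losses = []
        correct = 0.0
        total = 0.0
        for bi in batch_order:
            x, y, mask, lengths = _pad_batch(batches[bi])
            probs, cache = net.forward(x, mask, lengths, need_cache=True)
            loss, grads = net.backward(probs, y, cache)
            net.adam_step(grads, config.learning_rate)
            losses.append(loss)
            correct += float((((probs >= 0.5) == (y == 1)) * mask).sum())
            total += float(mask.sum())
        epoch_loss = float(np.mean(losses))
        fired = {"flip": 0, "reverse": 0, "noise": 0}
        for c in crops:
            for op in fired:
                fired[op] += op in c.applied
        log.append({"epoch": epoch, "loss": epoch_loss,
                    "accuracy": correct / total, "n_crops": len(crops),
                    "ops_fired": fired})
        if epoch_loss < best_loss - config.early_stop_min_delta:
            best_loss = epoch_loss
            stall = 0
        else:
            stall += 1
            if stall >= config.early_stop_patience:
                break
    return TrainedModel(config, net.state_dict(), samples[0].norm_ref, log)


def predict(model: TrainedModel,
            series: MinuteSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute in-bed probabilities and the thresholded binary track.

    The series must be normalized with the model's own statistics (checked by
    hash); output length equals input length.
    """
    if not series.normalized:
        raise IncompatibleNormalizationError("series is not normalized")
    if model.norm_stats_ref is not None and series.norm_ref != model.norm_stats_ref:
        raise IncompatibleNormalizationError(
            f"series normalized with {series.norm_ref}, "
            f"model expects {model.norm_stats_ref}"
        )
    net = model.network()
    T = series.n_minutes
    x = series.values[:, None, :]
    mask = np.ones((T, 1))
    probs = net.forward(x, mask, np.array([T]))[:, 0]
    return probs, (probs >= 0.5).astype(np.int8)


def _fold_partition(n_subjects: int, k: int, seed: int) -> list[list[int]]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_subjects)
    return [sorted(order[i::k].tolist()) for i in range(k)]


def cross_validate(cohort: list[MinuteSeries],
                   grid: list[ModelConfig],
                   aug_config: AugmentationConfig | None = None,
                   k: int = 10, seed: int = 0) -> list[CVResult]:
    """Subject-level k-fold cross-validation over a hyperparameter grid.

    ``cohort`` holds one *unnormalized* labelled series per subject. Folds
    partition subjects (never minutes); inside each fold the normalizer is
    fitted on the training subjects only and applied, frozen, to the
    validation subjects. Reports pooled minute accuracy per fold for every
    grid cell.
    """
    if len(cohort) < k:
        raise ConfigurationError(
            f"{len(cohort)} subjects cannot populate {k} folds"
        )
    if not grid:
        raise ConfigurationError("grid must be non-empty")
    folds = _fold_partition(len(cohort), k, seed)
    results = []
    for cfg in grid:
        fold_accs = []
        norm_hashes = []
        for fold_idx, val_ids in enumerate(folds):
            train_ids = [i for i in range(len(cohort)) if i not in val_ids]
            stats = fit_normalizer([cohort[i] for i in train_ids],
                                   source=f"cv_fold{fold_idx}")
            train_set = [apply_normalizer(cohort[i], stats) for i in train_ids]
            model = train(train_set, cfg, aug_config)
            assert model.norm_stats_ref == stats.stats_hash  # leakage guard
            correct = total = 0.0
            for i in val_ids:
                val_series = apply_normalizer(cohort[i], stats)
                _, track = predict(model, val_series)
                correct += float((track == val_series.labels).sum())
                total += float(track.size)
            fold_accs.append(correct / total)
            norm_hashes.append(stats.stats_hash)
        results.append(CVResult(cfg, tuple(fold_accs),
                                tuple(tuple(f) for f in folds),
                                tuple(norm_hashes)))
    return results


def select_model(cv_results: list[CVResult]) -> ModelConfig:
    """Sparsest grid cell within one standard error of the best mean accuracy.

    Ties on parameter count break deterministically by (n_layers,
    cells_per_layer) lexicographic order.
    """
    if not cv_results:
        raise ConfigurationError("no cross-validation results to select from")
    best = max(cv_results, key=lambda r: r.mean_accuracy)
    threshold = best.mean_accuracy - best.se_accuracy
    candidates = [r for r in cv_results if r.mean_accuracy >= threshold]
    candidates.sort(key=lambda r: (r.config.n_parameters, r.config.n_layers,
                                   r.config.cells_per_layer))
    return candidates[0].config


# ---------------------------------------------------------------------------
# persistence


def save_model(model: TrainedModel, path) -> None:
    """Checkpoint = npz weight container + JSON manifest; round-trips exactly."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.weights)
    manifest = {
        "config": asdict(model.config),
        "norm_stats_ref": model.norm_stats_ref,
        "training_log": model.training_log,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_model(path) -> TrainedModel:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as data:
        weights = {k: data[k].copy() for k in data.files}
    return TrainedModel(ModelConfig(**manifest["config"]), weights,
                        manifest["norm_stats_ref"], manifest["training_log"])
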
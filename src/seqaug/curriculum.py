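"""Two-stage training curriculum for augmentation-trained sequence models.

Stage 1 trains with stochastic augmentations applied online to each
mini-batch. Because the augmentations impose a prior (shift invariance,
spacing insensitivity) that can break the true cis-regulatory grammar,
stage 2 finetunes the best stage-1 checkpoint on the original, unperturbed
data at a reduced learning rate, restoring fidelity to the observed
biology while keeping the generalisation benefits.

When insertion is among the enabled augmentations every training batch has
length ``L + insert_max``; unaugmented data (validation, finetuning,
evaluation) is brought to the model's input length by ``evaluation_pad``,
which pads with fixed-seed random DNA so the padded input distribution
matches the stage-1 padding statistics and evaluation stays reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .adapters import ModelAdapter
from .augment import AugmentationConfig, augment_batch, random_onehot
from .seqdata import LabeledDataset, OneHotBatch

__all__ = [
    "CurriculumConfig",
    "TrainingHistory",
    "evaluation_pad",
    "train_stage1",
    "finetune_stage2",
    "train_two_stage",
    "grid_search",
    "pearson_per_task",
]


@dataclass
class CurriculumConfig:
    """Epoch counts, batch size and learning-rate schedule of the curriculum.

    ``stage2_lr_factor`` multiplies the stage-1 learning rate during
    finetuning (default 0.1). ``patience`` stops a stage early when the
    validation loss has not improved for that many epochs (None disables).
    """

    stage1_epochs: int = 10
    stage2_epochs: int = 5
    stage2_lr_factor: float = 0.1
    batch_size: int = 64
    patience: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage1_epochs < 0 or self.stage2_epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if not 0 < self.stage2_lr_factor <= 1:
            raise ValueError("stage2_lr_factor must be in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch losses/metrics for one stage plus the best checkpoint."""

    stage: str
    train_loss: list[float] = field(default_factory=list)
    valid_loss: list[float] = field(default_factory=list)
    valid_metric: list[np.ndarray] = field(default_factory=list)
    drawn_augmentations: list[list[tuple[str, ...]]] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_valid_loss(self) -> float:
        return self.valid_loss[self.best_epoch] if self.valid_loss else float("nan")

    @property
    def best_valid_metric(self) -> np.ndarray:
        return self.valid_metric[self.best_epoch]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e, (tl, vl, vm) in enumerate(
            zip(self.train_loss, self.valid_loss, self.valid_metric)
        ):
            row = {"stage": self.stage, "epoch": e, "train_loss": tl, "valid_loss": vl}
            for t, m in enumerate(np.atleast_1d(vm)):
                row[f"valid_metric_task{t}"] = m
            rows.append(row)
        return pd.DataFrame(rows)


def pearson_per_task(pred: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between predictions and labels, one value per task."""
    pred, y = np.atleast_2d(pred.T).T, np.atleast_2d(y.T).T
    out = np.empty(y.shape[1])
    for t in range(y.shape[1]):
        if np.std(pred[:, t]) == 0 or np.std(y[:, t]) == 0:
            out[t] = 0.0
        else:
            out[t] = stats.pearsonr(pred[:, t], y[:, t])[0]
    return out


def evaluation_pad(batch: OneHotBatch, target_length: int, seed: int = 0) -> OneHotBatch:
    """Pad unaugmented data to the model input length with fixed-seed random DNA.

    The pad is split evenly between the ends with the original sequence
    starting at offset ``ceil(pad / 2)``; the same seed always yields the
    same padding so evaluation is reproducible.
    """
    pad = target_length - batch.length
    if pad < 0:
        raise ValueError(
            f"target_length ({target_length}) must be >= sequence length ({batch.length})"
        )
    if pad == 0:
        return batch
    rng = np.random.default_rng(seed)
    left = (pad + 1) // 2
    ends = random_onehot(rng, (len(batch), pad))
    return OneHotBatch(
        np.concatenate([ends[:, :left], batch.data, ends[:, left:]], axis=1),
        batch.alphabet,
    )


def _pad_seed(seed: int) -> int:
    # fixed derivation so stage-1 validation, stage-2 and later evaluation
    # all see the identical padding
    return (seed * 2654435761 + 97) % (2**31)


def _prepare_eval(dataset: LabeledDataset, input_length: int, seed: int) -> tuple:
    x = evaluation_pad(dataset.x, input_length, _pad_seed(seed))
    return x.data, dataset.y


def _run_stage(
    adapter: ModelAdapter,
    train: LabeledDataset,
    valid: LabeledDataset,
    aug_config: AugmentationConfig | None,
    cur_config: CurriculumConfig,
    stage: str,
    epochs: int,
) -> TrainingHistory:
    history = TrainingHistory(stage=stage)
    if epochs == 0:
        return history
    ss = np.random.SeedSequence(cur_config.seed)
    data_rng, aug_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    n = len(train)
    bs = cur_config.batch_size
    xv, yv = _prepare_eval(valid, adapter.input_length, cur_config.seed)

    train_x_padded = None
    if aug_config is None and train.x.length != adapter.input_length:
        train_x_padded = evaluation_pad(
            train.x, adapter.input_length, _pad_seed(cur_config.seed)
        ).data

    best_loss, best_weights, best_epoch, since_best = np.inf, None, -1, 0
    for epoch in range(epochs):
        order = data_rng.permutation(n)
        epoch_losses, epoch_drawn = [], []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            if aug_config is not None:
                xb = OneHotBatch(train.x.data[idx], train.x.alphabet)
                xb, drawn = augment_batch(xb, aug_config, aug_rng, return_drawn=True)
                epoch_drawn.append(drawn)
                xa = xb.data
            else:
                base = train_x_padded if train_x_padded is not None else train.x.data
                xa = base[idx]
            if xa.shape[1] != adapter.input_length:
                raise ValueError(
                    f"configuration error: model input length {adapter.input_length} "
                    f"!= augmented batch length {xa.shape[1]}"
                )
            epoch_losses.append(adapter.train_on_batch(xa, train.y[idx]))
        vloss = adapter.evaluate(xv, yv)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.valid_loss.append(vloss)
        history.valid_metric.append(pearson_per_task(adapter.predict(xv), yv))
        history.drawn_augmentations.append(epoch_drawn)
        if vloss < best_loss:
            best_loss, best_weights, best_epoch, since_best = vloss, adapter.get_weights(), epoch, 0
        else:
            since_best += 1
            if cur_config.patience is not None and since_best > cur_config.patience:
                break
    history.best_epoch = best_epoch
    if best_weights is not None:
        adapter.set_weights(best_weights)  # checkpoint by validation loss
    return history


def train_stage1(
    adapter: ModelAdapter,
    train: LabeledDataset,
    valid: LabeledDataset,
    aug_config: AugmentationConfig | None,
    cur_config: CurriculumConfig,
) -> TrainingHistory:
    """Stage 1: online augmentation of every mini-batch before the gradient step.

    Validation uses unaugmented data padded to the model input length.
    The adapter is left holding the best weights by validation loss.
    """
    return _run_stage(
        adapter, train, valid, aug_config, cur_config, "stage1", cur_config.stage1_epochs
    )


def finetune_stage2(
    adapter: ModelAdapter,
    train: LabeledDataset,
    valid: LabeledDataset,
    cur_config: CurriculumConfig,
) -> TrainingHistory:
    """Stage 2: finetune on original, unperturbed data at a reduced rate.

    The adapter is expected to hold the best stage-1 weights; with
    ``stage2_epochs=0`` the weights are returned unchanged.
    """
    lr0 = adapter.learning_rate
    adapter.learning_rate = lr0 * cur_config.stage2_lr_factor
    try:
        return _run_stage(
            adapter, train, valid, None, cur_config, "stage2", cur_config.stage2_epochs
        )
    finally:
        adapter.learning_rate = lr0


def train_two_stage(
    adapter: ModelAdapter,
    train: LabeledDataset,
    valid: LabeledDataset,
    aug_config: AugmentationConfig | None,
    cur_config: CurriculumConfig,
) -> tuple[TrainingHistory, TrainingHistory]:
    """Run the full curriculum; returns (stage1, stage2) histories."""
    h1 = train_stage1(adapter, train, valid, aug_config, cur_config)
    h2 = finetune_stage2(adapter, train, valid, cur_config)
    return h1, h2


def grid_search(
    adapter_factory,
    train: LabeledDataset,
    valid: LabeledDataset,
    grid: list[AugmentationConfig | None],
    cur_config: CurriculumConfig,
) -> pd.DataFrame:
    """Train one model per augmentation config and rank by validation metric.

    A null-augmentation baseline row is always included. ``adapter_factory``
    is called with the required input length and must return a fresh
    adapter. Returns a DataFrame sorted by mean validation Pearson r
    (descending); write it with ``.to_csv(path, sep="\\t")`` for a TSV.
    """
    if not grid:
        raise ValueError("empty grid")
    full_grid: list[AugmentationConfig | None] = list(grid)
    if not any(g is None for g in full_grid):
        full_grid.append(None)  # baseline
    rows = []
    for i, cfg in enumerate(full_grid):
        extra = cfg.insert_max if cfg is not None and "insertion" in cfg.enabled else 0
        adapter = adapter_factory(train.x.length + extra)
        h1, h2 = train_two_stage(adapter, train, valid, cfg, cur_config)
        hist = h2 if h2.valid_metric else h1
        metric = np.mean(hist.best_valid_metric)
        rows.append(
            {
                "config_index": i,
                "config": "baseline" if cfg is None else ",".join(cfg.enabled),
                "valid_loss": hist.best_valid_loss,
                "valid_metric_mean": float(metric),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("valid_metric_mean", ascending=False)
        .reset_index(drop=True)
    )
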
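"""Two-stage training with early stopping and best-weight restoration.

Stage 1 optimizes the chosen loss on the training set and watches
validation accuracy after every epoch; training stops when accuracy has
not strictly improved for ``patience`` consecutive epochs (or at the
epoch cap), and the weights of the best-validation-accuracy epoch are
reinstated.  Stage 2 merges the validation set into the training set and
keeps optimizing; the loss restricted to the former validation trials is
monitored and training stops as soon as it drops below the best (lowest)
stage-1 validation loss, with a safety epoch cap because that criterion
need not ever trigger.

All stochastic pieces (initialization, batch shuffling, dropout) draw
from generators derived from ``TrainConfig.seed``, so runs are bit
reproducible on a fixed platform.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .core_data import ConfigurationError, EpochSet
from .filterbank import FilterBankSpec, apply_filterbank, make_default_bank
from .losses_metrics import MetricsReport, batch_loss, batch_loss_grad, confusion, metrics_from_confusion
from .model import Model
from .nnops import Adam

__all__ = ["TrainConfig", "TrainHistory", "train_two_stage", "evaluate",
           "set_global_seed"]


@dataclasses.dataclass
class TrainConfig:
    """Optimization settings; defaults follow the published protocol."""

    batch_size: int = 32
    learning_rate: float = 0.001
    optimizer: str = "adam"
    max_epochs_stage1: int = 100
    patience: int = 50
    max_epochs_stage2: int = 200
    loss: str = "ece"  # {"ce", "ece"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience > self.max_epochs_stage1:
            raise ConfigurationError(
                f"patience {self.patience} exceeds max_epochs_stage1 "
                f"{self.max_epochs_stage1}")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss not in ("ce", "ece"):
            raise ConfigurationError(f"loss must be 'ce' or 'ece', got {self.loss!r}")


@dataclasses.dataclass
class TrainHistory:
    """Per-epoch records of both stages plus stopping summary."""

    records: list[dict] = dataclasses.field(default_factory=list)
    best_val_accuracy: float = 0.0
    best_epoch: int = 0
    stage1_best_val_loss: float = float("inf")
    stage2_criterion_met: bool = False

    def append(self, stage: int, epoch: int, train_loss: float,
               val_loss: float, val_accuracy: float) -> None:
        self.records.append({
            "stage": stage, "epoch": epoch,
            "train_loss": float(train_loss),
            "val_loss": float(val_loss),
            "val_accuracy": float(val_accuracy),
        })

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        path = Path(path)
        pd.DataFrame(self.records).to_csv(path, index=False)
        return path


def set_global_seed(seed: int) -> np.random.Generator:
    """Seed numpy's legacy global state and return a fresh Generator."""
    np.random.seed(seed % 2**32)
    return np.random.default_rng(seed)


def _epoch_pass(model: Model, x: np.ndarray, y: np.ndarray, opt: Adam,
                batch_size: int, loss_kind: str,
                rng: np.random.Generator) -> float:
    """One optimization epoch over shuffled mini-batches; mean batch loss."""
    order = rng.permutation(len(y))
    total, seen = 0.0, 0
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        xb = np.ascontiguousarray(x[idx])
        yb = y[idx]
        logp = model.forward(xb, mode="train")
        loss = batch_loss(logp, yb, kind=loss_kind)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss on batch at {start}")
        opt.zero_grad()
        model.backward(batch_loss_grad(logp, yb, kind=loss_kind))
        opt.step()
        total += loss * len(idx)
        seen += len(idx)
    return total / seen


def _eval_logits(model: Model, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    outs = [model.forward(np.asarray(x[i : i + batch_size], dtype=np.float64),
                          mode="eval")
            for i in range(0, len(x), batch_size)]
    return np.concatenate(outs, axis=0)


def train_two_stage(
    model: Model,
    train: EpochSet,
    val: EpochSet,
    config: TrainConfig,
    graph=None,
    bank: FilterBankSpec | None = None,
) -> tuple[Model, TrainHistory]:
    """Run both training stages in place; returns the model and history."""
    if train.n_trials == 0 or val.n_trials == 0:
        raise ConfigurationError("train and validation sets must be non-empty")
    if train.n_channels != model.config.n_channels:
        raise ConfigurationError(
            f"data has {train.n_channels} channels, model expects "
            f"{model.config.n_channels}")
    if graph is not None and graph.n_channels != model.config.n_channels:
        raise ConfigurationError("propagation matrix does not match channel count")
    bank = bank or make_default_bank()
    # band tensors are precomputed once and held in float32 to bound memory
    x_tr = apply_filterbank(train, bank).data.astype(np.float32)
    x_val = apply_filterbank(val, bank).data.astype(np.float32)
    y_tr, y_val = train.labels, val.labels

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory()

    # ---- stage 1: early stopping on validation accuracy ----------------
    best_state: dict[str, np.ndarray] | None = None
    since_improve = 0
    for epoch in range(1, config.max_epochs_stage1 + 1):
        train_loss = _epoch_pass(model, x_tr, y_tr, opt, config.batch_size,
                                 config.loss, rng)
        logp = _eval_logits(model, x_val)
        val_loss = batch_loss(logp, y_val, kind=config.loss)
        val_acc = float((logp.argmax(axis=1) == y_val).mean())
        history.append(1, epoch, train_loss, val_loss, val_acc)
        history.stage1_best_val_loss = min(history.stage1_best_val_loss, val_loss)
        if val_acc > history.best_val_accuracy or best_state is None:
            history.best_val_accuracy = val_acc
            history.best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            since_improve = 0
        else:
            since_improve += 1
        if since_improve >= config.patience:
            break
    model.load_state_arrays(best_state)

    # ---- stage 2: merge validation, monitor its loss --------------------
    x_all = np.concatenate([x_tr, x_val], axis=0)
    y_all = np.concatenate([y_tr, y_val], axis=0)
    former_val = np.arange(len(y_tr), len(y_all))
    for epoch in range(1, config.max_epochs_stage2 + 1):
        train_loss = _epoch_pass(model, x_all, y_all, opt, config.batch_size,
                                 config.loss, rng)
        logp = _eval_logits(model, x_all[former_val])
        monitored = batch_loss(logp, y_all[former_val], kind=config.loss)
        val_acc = float((logp.argmax(axis=1) == y_all[former_val]).mean())
        history.append(2, epoch, train_loss, monitored, val_acc)
        if monitored < history.stage1_best_val_loss:
            history.stage2_criterion_met = True
            break
    return model, history


def evaluate(model: Model, test: EpochSet,
             bank: FilterBankSpec | None = None) -> MetricsReport:
    """Eval-mode forward, argmax decision (first max wins), full metrics."""
    if test.n_channels != model.config.n_channels:
        raise ConfigurationError(
            f"data has {test.n_channels} channels, model expects "
            f"{model.config.n_channels}")
    bank = bank or make_default_bank()
    x = apply_filterbank(test, bank).data
    logp = _eval_logits(model, x)
    preds = logp.argmax(axis=1)
    cm = confusion(test.labels, preds, model.config.n_classes)
    return metrics_from_confusion(cm)
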
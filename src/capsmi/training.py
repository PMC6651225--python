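"""Mini-batch SGD training, accuracy evaluation, early stopping, grid search.

The optimizer is classical (heavy-ball) momentum SGD with the source
study's settings: batch 50, learning rate 0.01, momentum 0.7, 500 epochs.
The same loop trains both the capsule network and the ShallowNet baseline;
a model only needs ``params``, ``loss_and_grads`` and ``predict``.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .capsnet import CapsNetConfig, CapsNetModel

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "History",
    "GridSpec",
    "fit_sgd",
    "train_model",
    "evaluate",
    "early_stop_monitor",
    "split_validation",
    "grid_search",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 50
    epochs: int = 500
    learning_rate: float = 0.01
    momentum: float = 0.7
    seed: int = 0
    early_stopping: bool = False
    patience: int = 10
    validation_fraction: float = 0.2
    precision: str = "float32"  # or "float64"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.early_stopping and not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.precision not in ("float32", "float64"):
            raise ValueError("precision must be 'float32' or 'float64'")


@dataclass
class History:
    """Per-epoch curves; val_* are filled when a validation/test set is given."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        d = {"epoch": np.arange(1, len(self) + 1),
             "train_loss": self.train_loss, "train_acc": self.train_acc}
        if self.val_loss:
            d["val_loss"] = self.val_loss
            d["val_acc"] = self.val_acc
        return pd.DataFrame(d)


def split_validation(X: np.ndarray, y: np.ndarray, fraction: float):
    """Hold out the last ``fraction`` of trials per class (stratified tail)."""
    y = np.asarray(y)
    val_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_val = max(1, int(round(fraction * len(idx))))
        val_idx.extend(idx[-n_val:])
    val_mask = np.zeros(len(y), dtype=bool)
    val_mask[val_idx] = True
    return (X[~val_mask], y[~val_mask]), (X[val_mask], y[val_mask])


def early_stop_monitor(val_losses, patience: int):
    """Apply the early-stopping rule to a loss trace.

    Stops after the first epoch at which the validation loss has not
    strictly improved for ``patience`` consecutive epochs.  Returns
    ``(stop_epoch or None, best_epoch)``, both 1-based; ``best_epoch`` is
    the argmin of the (possibly truncated) trace.
    """
    if patience < 1:
        raise ValueError("patience must be >= 1")
    best = np.inf
    best_epoch = 0
    stale = 0
    for epoch, loss in enumerate(val_losses, start=1):
        if loss < best:
            best, best_epoch, stale = loss, epoch, 0
        else:
            stale += 1
            if stale >= patience:
                return epoch, best_epoch
    return None, best_epoch if best_epoch else None


def fit_sgd(model, X: np.ndarray, y: np.ndarray, cfg: TrainConfig,
            eval_set: tuple[np.ndarray, np.ndarray] | None = None):
    """Train ``model`` in place; returns the History.

    With early stopping enabled, ``eval_set`` (or a stratified 20% tail
    split when absent) is monitored and the best-validation parameters are
    restored before returning; otherwise the final-epoch parameters stand.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=np.int64)
    if len(X) == 0:
        raise ValueError("empty training set")
    if cfg.early_stopping and eval_set is None:
        (X, y), eval_set = split_validation(X, y, cfg.validation_fraction)
    rng = np.random.default_rng(cfg.seed)
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    history = History()
    best_val = np.inf
    best_params = None
    stale = 0
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(X))
        losses, correct = [], 0
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads, preds = model.loss_and_grads(X[idx], y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            for k, g in grads.items():
                velocity[k] = cfg.momentum * velocity[k] - cfg.learning_rate * g
                model.params[k] += velocity[k]
            losses.append(loss * len(idx))
            correct += int((preds == y[idx]).sum())
        history.train_loss.append(float(np.sum(losses) / len(X)))
        history.train_acc.append(correct / len(X))
        if eval_set is not None:
            Xv, yv = eval_set
            vloss = model.batch_loss(Xv, yv)
            vacc = float((model.predict(Xv) == np.asarray(yv)).mean())
            history.val_loss.append(vloss)
            history.val_acc.append(vacc)
            if cfg.early_stopping:
                if vloss < best_val:
                    best_val, stale = vloss, 0
                    best_params = {k: v.copy() for k, v in model.params.items()}
                else:
                    stale += 1
                    if stale >= cfg.patience:
                        break
    if cfg.early_stopping and best_params is not None:
        model.params = best_params
    return history


def train_model(
    images: np.ndarray,
    labels: np.ndarray,
    model_cfg: CapsNetConfig = CapsNetConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    eval_set: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[CapsNetModel, History]:
    """Train a capsule network on images (n, 3, 14, 14) with labels 0/1."""
    dtype = np.float64 if train_cfg.precision == "float64" else np.float32
    model = CapsNetModel(model_cfg, seed=train_cfg.seed, dtype=dtype)
    history = fit_sgd(model, images, labels, train_cfg, eval_set=eval_set)
    return model, history


def evaluate(model, X: np.ndarray, y: np.ndarray) -> float:
    """Accuracy = 1 - misclassification rate, with argmax/low-index ties."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    return float((model.predict(np.asarray(X)) == y).mean())


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid of the source study's optimization experiment."""

    routing_iters: tuple[int, ...] = (1, 2, 3)
    reconstruction: tuple[bool, ...] = (True, False)
    conv_channels: tuple[int, ...] = (256, 128, 64, 32, 16, 8, 4)
    primary_channels: tuple[int, ...] = (128, 64, 32, 16, 8, 4)
    primary_dim: tuple[int, ...] = (32, 16, 8, 4)
    mi_dim: tuple[int, ...] = (16, 8, 4)

    def points(self):
        yield from itertools.product(
            self.routing_iters, self.reconstruction, self.conv_channels,
            self.primary_channels, self.primary_dim, self.mi_dim,
        )


def grid_search(
    grid: GridSpec,
    train_data: tuple[np.ndarray, np.ndarray],
    test_data: tuple[np.ndarray, np.ndarray],
    train_cfg: TrainConfig = TrainConfig(),
    base_cfg: CapsNetConfig = CapsNetConfig(),
) -> pd.DataFrame:
    """Train/evaluate every grid point with a shared seed; rank by accuracy.

    Invalid grid points (e.g. an empty capsule grid) are skipped with a
    warning and recorded with NaN accuracy.
    """
    rows = []
    Xtr, ytr = train_data
    for routing, rec, conv, pri, pri_dim, mi_dim in grid.points():
        row = {
            "routing": routing, "reconstruction": rec, "conv_channels": conv,
            "primary_channels": pri, "primary_dim": pri_dim, "mi_dim": mi_dim,
        }
        try:
            cfg = replace(
                base_cfg, routing_iters=routing, reconstruction=rec,
                conv_channels=conv, primary_channels=pri,
                primary_dim=pri_dim, mi_dim=mi_dim,
            )
            model, _ = train_model(Xtr, ytr, cfg, train_cfg)
            row["accuracy"] = evaluate(model, *test_data)
        except (ValueError, FloatingPointError) as exc:
            warnings.warn(f"skipping invalid grid point {row}: {exc}")
            logger.warning("grid point %s skipped: %s", row, exc)
            row["accuracy"] = np.nan
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.sort_values("accuracy", ascending=False, ignore_index=True)
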
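"""Seeded training, evaluation, and last-layer-only fine-tuning.

Defaults follow the reference regime: Adam, learning rate 1e-3 from scratch
and 1e-4 for fine-tuning, 100 epochs, batch size 128, seed 123.  There is no
learning-rate schedule, weight decay, or early stopping.  Runs are bit-wise
reproducible for a fixed seed on a given platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from . import _autodiff as ad
from ._autodiff import Tensor
from ._nn import Adam
from .head_model import ModelConfig, SensorNet, build_model, load_checkpoint
from .spectrogram import MultiChannelWindow, StftParams, convert_batch

__all__ = [
    "TrainConfig",
    "SpectrogramDataset",
    "dataset_from_windows",
    "cross_entropy",
    "train",
    "fine_tune",
    "evaluate",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    finetune_learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 128
    seed: int = 123
    val_fraction: float = 0.2
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8

    def __post_init__(self):
        if min(self.learning_rate, self.finetune_learning_rate) <= 0:
            raise ValueError("learning rates must be positive")
        if self.finetune_learning_rate >= self.learning_rate:
            raise ValueError("fine-tune learning rate must be below the scratch rate")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SpectrogramDataset:
    """Spectrogram stacks (N, C, H, W) with integer labels (N,)."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        X = np.asarray(self.X, dtype=np.float32)
        y = np.asarray(self.y, dtype=np.int64)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 4:
            raise ValueError(f"X must be (N, C, H, W), got {X.shape}")
        if y.shape != (X.shape[0],):
            raise ValueError("labels must be one integer per window")
        if X.shape[0] == 0:
            raise ValueError("dataset is empty")
        if y.min() < 0:
            raise ValueError("labels must be non-negative")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_classes(self) -> int:
        return int(self.y.max()) + 1

    def subset(self, idx) -> "SpectrogramDataset":
        return SpectrogramDataset(self.X[idx], self.y[idx])


def dataset_from_windows(windows: list[MultiChannelWindow],
                         target_size: tuple[int, int],
                         stft_params: StftParams | None = None) -> SpectrogramDataset:
    """Convert labelled raw windows into a spectrogram dataset."""
    stacks = convert_batch(windows, target_size, stft_params)
    labels = [w.label for w in windows]
    if any(lbl is None for lbl in labels):
        raise ValueError("all windows must carry a label")
    return SpectrogramDataset(np.stack([s.values for s in stacks]),
                              np.asarray(labels))


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood, computed in the log domain."""
    n, k = logits.shape
    onehot = np.zeros((n, k), dtype=logits.dtype)
    onehot[np.arange(n), labels] = 1.0
    logp = ad.log_softmax(logits, axis=-1)
    return ad.mul(ad.tsum(ad.mul(logp, onehot)), -1.0 / n)


def _stratified_split(y: np.ndarray, val_fraction: float, seed: int):
    idx = np.arange(y.size)
    train_idx, val_idx = train_test_split(
        idx, test_size=val_fraction, random_state=seed, stratify=y)
    return np.sort(train_idx), np.sort(val_idx)


def _run_epoch(model: SensorNet, X, y, batch_size, optimizer=None, rng=None):
    """One pass over (X, y); trains when an optimizer is given."""
    n = X.shape[0]
    order = rng.permutation(n) if rng is not None else np.arange(n)
    total_loss, correct = 0.0, 0
    for start in range(0, n, batch_size):
        batch = order[start:start + batch_size]
        logits = model(X[batch])
        loss = cross_entropy(logits, y[batch])
        if not np.isfinite(loss.data):
            raise FloatingPointError("non-finite training loss")
        if optimizer is not None:
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        total_loss += float(loss.data) * batch.size
        correct += int((np.argmax(logits.data, axis=1) == y[batch]).sum())
    return total_loss / n, correct / n


def train(model: SensorNet, dataset: SpectrogramDataset,
          cfg: TrainConfig = TrainConfig(), *,
          learning_rate: float | None = None) -> dict:
    """Train in place; returns a history dict with per-epoch metrics.

    The dataset is split 80/20 (stratified, seeded) into train/validation.
    """
    if dataset.n_classes > model.cfg.n_classes or dataset.y.max() >= model.cfg.n_classes:
        raise ValueError(
            f"dataset labels reach {dataset.y.max()}, model has "
            f"{model.cfg.n_classes} classes"
        )
    lr = cfg.learning_rate if learning_rate is None else learning_rate
    train_idx, val_idx = _stratified_split(dataset.y, cfg.val_fraction, cfg.seed)
    Xtr, ytr = dataset.X[train_idx], dataset.y[train_idx]
    Xva, yva = dataset.X[val_idx], dataset.y[val_idx]
    optimizer = Adam(model.parameters(), lr=lr, betas=cfg.betas, eps=cfg.eps)
    rng = np.random.default_rng(cfg.seed)
    history = {"train_loss": [], "train_accuracy": [],
               "val_loss": [], "val_accuracy": []}
    for _ in range(cfg.epochs):
        tr_loss, tr_acc = _run_epoch(model, Xtr, ytr, cfg.batch_size,
                                     optimizer=optimizer, rng=rng)
        va_loss, va_acc = _run_epoch(model, Xva, yva, cfg.batch_size)
        history["train_loss"].append(tr_loss)
        history["train_accuracy"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_accuracy"].append(va_acc)
    return history


def fine_tune(pretrained_trunk, new_dataset: SpectrogramDataset,
              cfg: TrainConfig = TrainConfig()) -> tuple[SensorNet, dict]:
    """Adapt a pretrained trunk to a new task.

    Only the final classification layer is replaced and re-initialised; all
    other weights start exactly at their checkpoint values.  All weights are
    then optimised at the fine-tuning learning rate (default 1e-4).

    ``pretrained_trunk`` may be a checkpoint path or a :class:`SensorNet`.
    """
    n_classes = new_dataset.n_classes
    if isinstance(pretrained_trunk, SensorNet):
        src = pretrained_trunk
        cfg_new = ModelConfig.from_dict({**src.cfg.to_dict(), "n_classes": n_classes})
        model = build_model(cfg_new, seed=cfg.seed)
        final = model.final_layer_names()
        src_params = dict(src.named_parameters())
        for name, p in model.named_parameters():
            if name in final:
                continue
            p.data = src_params[name].data.copy()
    else:
        model = load_checkpoint(pretrained_trunk, n_classes=n_classes, seed=cfg.seed)
    history = train(model, new_dataset, cfg,
                    learning_rate=cfg.finetune_learning_rate)
    return model, history


def evaluate(model: SensorNet, dataset: SpectrogramDataset,
             batch_size: int = 128) -> dict:
    """Accuracy, per-class accuracy, and confusion matrix."""
    preds = np.concatenate([
        model.predict(dataset.X[i:i + batch_size])
        for i in range(0, len(dataset), batch_size)
    ])
    k = max(model.cfg.n_classes, dataset.n_classes)
    cm = confusion_matrix(dataset.y, preds, labels=np.arange(k))
    per_class = np.divide(np.diag(cm), cm.sum(axis=1),
                          out=np.full(k, np.nan), where=cm.sum(axis=1) > 0)
    return {
        "accuracy": float((preds == dataset.y).mean()),
        "per_class_accuracy": per_class,
        "confusion_matrix": cm,
    }
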
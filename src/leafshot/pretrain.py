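"""Source-domain training of the backbone.

All layers are trainable at this stage.  Training uses categorical
cross-entropy, Adam with the standard defaults, batch size 16, and a
stratified per-class validation holdout (default 20%).  The epoch with the
best validation accuracy is kept, with early stopping after ``patience``
epochs without improvement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .arch import ModelSpec
from .data import ClassIndexedDataset, stratified_split_indices


@dataclass
class TrainConfig:
    batch_size: int = 16
    optimizer: str = "adam_default"
    loss: str = "categorical_cross_entropy"
    validation_fraction: float = 0.20
    max_epochs: int = 50
    patience: int = 5
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam_default":
            raise ValueError("only the adam_default optimizer is supported")
        if self.loss != "categorical_cross_entropy":
            raise ValueError("only categorical cross-entropy is supported")


def evaluate(model: ModelSpec, X: np.ndarray, y: np.ndarray, batch_size: int = 64):
    """(mean cross-entropy, accuracy) of the model on labeled images."""
    logits = model.logits(X, batch_size=batch_size)
    loss, p, _ = nn.softmax_xent(logits, np.asarray(y))
    acc = float((p.argmax(axis=1) == np.asarray(y)).mean())
    return loss, acc


def pretrain(model: ModelSpec, source: ClassIndexedDataset, cfg: TrainConfig):
    """Train all layers on the source domain; return (best model, history).

    The model is not modified in place: a copy carrying the weights of the
    best-validation-accuracy epoch is returned.  ``history`` is a DataFrame
    with per-epoch train loss/accuracy and validation loss/accuracy.
    """
    if model.head_classes != source.n_classes:
        raise ValueError(
            f"model head has {model.head_classes} classes but the source domain "
            f"has {source.n_classes}")
    if min(source.counts) < 2:
        raise ValueError("every source class needs >= 2 images for a validation split")

    X, y = source.stacked()
    train_idx, val_idx = stratified_split_indices(y, cfg.validation_fraction, seed=cfg.seed)
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]

    work = model.copy()
    layers = [layer for (_, layer) in work._ordered_impl()]
    opt = nn.Adam(layers, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)

    best = work.copy()
    best_val = -1.0
    best_val_loss = np.inf
    best_epoch = -1
    rows = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(Xtr))
        losses, correct = [], 0
        for lo in range(0, len(order), cfg.batch_size):
            sel = order[lo:lo + cfg.batch_size]
            h = Xtr[sel]
            for layer in layers:
                h = layer.forward(h, train=True)
            loss, p, grad = nn.softmax_xent(h, ytr[sel])
            d = grad
            for layer in reversed(layers):
                d = layer.backward(d)
            opt.step()
            losses.append(loss * len(sel))
            correct += int((p.argmax(axis=1) == ytr[sel]).sum())
        val_loss, val_acc = evaluate(work, Xval, yval)
        rows.append({
            "epoch": epoch,
            "loss": float(np.sum(losses) / len(Xtr)),
            "accuracy": correct / len(Xtr),
            "val_loss": val_loss,
            "val_accuracy": val_acc,
        })
        if val_acc > best_val or (val_acc == best_val and val_loss < best_val_loss):
            best_val = val_acc
            best_val_loss = val_loss
            best_epoch = epoch
            best = work.copy()
        elif epoch - best_epoch >= cfg.patience:
            break
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best_epoch
    return best, history
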
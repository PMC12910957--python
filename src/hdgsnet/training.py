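"""Supervised training of the occupancy network.

Follows the published protocol: Adam (initial learning rate 1e-4), mean
squared error loss for occupancy regression (binary cross-entropy for the
classification head), mean absolute error / accuracy as the monitored
metric, batch size 64, and a 3:1:1 train/validation/test split.  Callbacks
halve the learning rate when the validation loss plateaus and keep the
best-validation weights, which are restored when training ends.

All randomness (split shuffles, batch order, dropout masks, weight
initialization) is driven by explicit integer seeds, so identical
seeds and configurations reproduce identical histories on CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .genome_io import DatasetContainer
from .model import HDGSModelConfig, HDGSNet, build_hdgs
from .nn import Adam

__all__ = [
    "TrainingConfig", "split_311", "train", "predict",
    "crossvalidate_classifier",
]

_EPS = 1e-7


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 200
    loss: str = "mse"             # 'mse' | 'bce'
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    plateau_min_delta: float = 1e-4   # improvements smaller than this count
    min_lr: float = 1e-6              # as a plateau (ReduceLROnPlateau-style)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss not in ("mse", "bce"):
            raise ValueError(f"unknown loss {self.loss!r}")


def split_311(container: DatasetContainer, seed: int = 0,
              ) -> tuple[DatasetContainer, DatasetContainer, DatasetContainer]:
    """Shuffle and split 3:1:1 (60/20/20 with largest-remainder rounding)."""
    n = len(container)
    if n < 5:
        raise ValueError("need at least 5 samples for a 3:1:1 split")
    quotas = np.array([0.6, 0.2, 0.2]) * n
    sizes = np.floor(quotas).astype(int)
    remainder = n - sizes.sum()
    order = np.argsort(-(quotas - sizes), kind="stable")
    for i in range(remainder):
        sizes[order[i]] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    a, b = sizes[0], sizes[0] + sizes[1]
    return (container.subset(perm[:a]), container.subset(perm[a:b]),
            container.subset(perm[b:]))


def _loss_and_grad(pred: np.ndarray, y: np.ndarray, kind: str,
                   ) -> tuple[float, np.ndarray]:
    n = y.size
    if kind == "mse":
        diff = pred - y
        return float(np.mean(diff ** 2)), (2.0 / n) * diff
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    loss = -float(np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    grad = (p - y) / (p * (1 - p)) / n
    grad[(pred <= _EPS) | (pred >= 1 - _EPS)] = 0.0
    return loss, grad


def _metric(pred: np.ndarray, y: np.ndarray, kind: str) -> float:
    if kind == "mse":
        return float(np.mean(np.abs(pred - y)))          # MAE
    return float(np.mean((pred > 0.5) == (y > 0.5)))     # accuracy


def predict(model: HDGSNet, container: DatasetContainer | np.ndarray,
            batch_size: int = 256) -> np.ndarray:
    """Evaluation-mode predictions, one per sample, in input order."""
    feats = container.features if isinstance(container, DatasetContainer) \
        else np.asarray(container)
    out = [model.forward(feats[i:i + batch_size])
           for i in range(0, len(feats), batch_size)]
    return np.concatenate(out) if out else np.zeros(0, dtype=np.float32)


def train(model: HDGSNet,
          splits: tuple[DatasetContainer, DatasetContainer] |
                  tuple[DatasetContainer, DatasetContainer, DatasetContainer],
          config: TrainingConfig) -> pd.DataFrame:
    """Train in place; returns the per-epoch history.

    History columns: epoch, lr, train_loss, val_loss, val_metric (MAE for
    regression, accuracy for classification).  The weights with the lowest
    validation loss are restored before returning.  A NaN loss aborts with
    a diagnostic.
    """
    train_set, val_set = splits[0], splits[1]
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation splits must be nonempty")
    x_tr, y_tr = train_set.features, train_set.labels.astype(np.float64)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    history: dict[str, list] = {k: [] for k in
                                ("epoch", "lr", "train_loss", "val_loss",
                                 "val_metric")}
    best = {"loss": np.inf, "state": model.state(), "epoch": -1}
    plateau_ref = np.inf
    wait = 0
    for epoch in range(config.epochs):
        perm = rng.permutation(len(train_set))
        batch_losses = []
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start:start + config.batch_size]
            pred = model.forward(x_tr[idx], train=True)
            loss, grad = _loss_and_grad(pred.astype(np.float64), y_tr[idx],
                                        config.loss)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, "
                    f"batch {start // config.batch_size} (lr={opt.lr:g})")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            batch_losses.append(loss)
        val_pred = predict(model, val_set,
                           batch_size=config.batch_size).astype(np.float64)
        y_val = val_set.labels.astype(np.float64)
        val_loss, _ = _loss_and_grad(val_pred, y_val, config.loss)
        history["epoch"].append(epoch)
        history["lr"].append(opt.lr)
        history["train_loss"].append(float(np.mean(batch_losses)))
        history["val_loss"].append(val_loss)
        history["val_metric"].append(_metric(val_pred, y_val, config.loss))
        if val_loss < best["loss"]:
            best = {"loss": val_loss, "state": model.state(), "epoch": epoch}
        if val_loss < plateau_ref - config.plateau_min_delta:
            plateau_ref = val_loss
            wait = 0
        else:
            wait += 1
            if wait >= config.plateau_patience:
                opt.lr = max(opt.lr * config.plateau_factor, config.min_lr)
                plateau_ref = val_loss
                wait = 0
    model.load_state(best["state"])
    df = pd.DataFrame(history)
    df.attrs["best_epoch"] = best["epoch"]
    df.attrs["best_val_loss"] = best["loss"]
    return df


def crossvalidate_classifier(model_config: HDGSModelConfig,
                             features: np.ndarray, labels: np.ndarray,
                             k: int = 5, seed: int = 0,
                             train_config: TrainingConfig | None = None,
                             ) -> dict:
    """Stratified k-fold cross-validation of the classification head.

    Builds a fresh model per fold, trains on the fold's training portion
    (with an internal 80/20 train/validation split for the callbacks) and
    scores accuracy on the held-out fold.
    """
    labels = np.asarray(labels).astype(np.float32)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("cross-validation needs both classes present")
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the minority class count {counts.min()}")
    if model_config.head != "classification":
        raise ValueError("model_config must use the classification head")
    cfg = train_config or TrainingConfig(loss="bce", epochs=5, seed=seed)
    if cfg.loss != "bce":
        raise ValueError("classifier cross-validation requires the bce loss")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accuracies = []
    dummy = np.array(["."] * len(labels), dtype=object)
    for fold, (tr, te) in enumerate(skf.split(features, labels)):
        inner_rng = np.random.default_rng(seed + 1000 + fold)
        tr = inner_rng.permutation(tr)
        n_val = max(1, int(round(0.2 * tr.size)))
        val_idx, tr_idx = tr[:n_val], tr[n_val:]

        def sub(idx):
            return DatasetContainer(features[idx], labels[idx], dummy[idx],
                                    np.zeros(idx.size, dtype=np.int64),
                                    np.array(["+"] * idx.size))
        model = build_hdgs(model_config, seed=seed + fold)
        train(model, (sub(tr_idx), sub(val_idx)), cfg)
        pred = predict(model, features[te])
        accuracies.append(float(np.mean((pred > 0.5) == (labels[te] > 0.5))))
    return {"fold_accuracy": accuracies,
            "mean_accuracy": float(np.mean(accuracies))}
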
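"""Training: binary cross-entropy, Adam, best-accuracy checkpointing.

The loss attaches to the voted (sector-mean) positive probability by
default; an alternative mode sums per-sector BCE terms.  After every epoch
the image-level training accuracy is computed and the parameters of the
highest-accuracy epoch (ties -> earliest) are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .data import SectorDataset
from .vvit import PROB_EPS, VvitModel, predict_binary


@dataclass
class TrainConfig:
    epochs: int = 200
    lr: float = 1e-3
    betas: Tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 0.0
    amsgrad: bool = False
    batch_size: int = 32
    seed: int = 0
    loss_mode: str = "voted"  # or "per_sector_sum"
    dropout: float = 0.0  # inverted dropout on token embeddings and head layers
    monitor: str = "train"  # checkpoint monitor: "train" or "validation"
    val_fraction: float = 0.15  # held-out patient fraction when monitor="validation"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def bce_loss(prob_positive, label) -> float:
    """Mean binary cross-entropy with probabilities clamped to [1e-7, 1-1e-7]."""
    p = np.clip(np.asarray(prob_positive, dtype=np.float64), PROB_EPS, 1 - PROB_EPS)
    y = np.asarray(label, dtype=np.float64)
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))


class Adam:
    """Adam optimizer over a flat dict of parameter arrays."""

    def __init__(self, params: Dict[str, np.ndarray], lr=1e-3, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=0.0, amsgrad=False):
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay, self.amsgrad = weight_decay, amsgrad
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.vhat_max = {k: np.zeros_like(v) for k, v in params.items()} if amsgrad else None
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in params.items():
            g = grads.get(k)
            if g is None:
                continue
            g = np.asarray(g, dtype=p.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            vhat = self.v[k] / bc2
            if self.amsgrad:
                np.maximum(self.vhat_max[k], vhat, out=self.vhat_max[k])
                vhat = self.vhat_max[k]
            p -= self.lr * (self.m[k] / bc1) / (np.sqrt(vhat) + self.eps)


def predict_probs(model: VvitModel, dataset: SectorDataset,
                  batch_size: int = 64) -> np.ndarray:
    """Per-slice per-sector positive probabilities, shape (n_slices, n_sectors)."""
    names = [s.name for s in model.sectors]
    out = np.empty((dataset.n, len(names)), dtype=np.float64)
    for start in range(0, dataset.n, batch_size):
        rows = np.arange(start, min(start + batch_size, dataset.n))
        pt = model.forward(dataset.batch(rows))
        for j, name in enumerate(names):
            out[rows, j] = pt.per_sector[name][:, 1]
    return out


def image_accuracy(model: VvitModel, dataset: SectorDataset,
                   batch_size: int = 64) -> float:
    probs = predict_probs(model, dataset, batch_size)
    voted = probs.mean(axis=1)
    pred = (voted >= 0.5).astype(int)
    return float(np.mean(pred == dataset.y))


@dataclass
class TrainResult:
    best_params: Dict[str, np.ndarray]
    best_epoch: int
    best_accuracy: float
    history: List[dict] = field(default_factory=list)
    diverged: bool = False


def _validation_split(train_set: SectorDataset, val_fraction: float, seed: int):
    """Stratified per-patient holdout used only to pick the best checkpoint."""
    labels = train_set.patient_labels()
    rng = np.random.default_rng(seed)
    val_pids = set()
    for cls in (0, 1):
        ids = sorted(p for p, l in labels.items() if l == cls)
        if len(ids) < 2:
            continue
        n_val = int(np.clip(round(val_fraction * len(ids)), 1, len(ids) - 1))
        val_pids.update(rng.choice(ids, size=n_val, replace=False))
    val_mask = np.isin(train_set.patient_ids, sorted(val_pids))
    if not val_mask.any() or val_mask.all():
        raise ValueError("validation split would leave an empty partition")
    return (train_set.subset(np.where(~val_mask)[0]),
            train_set.subset(np.where(val_mask)[0]))


def train(model: VvitModel, train_set: SectorDataset,
          config: Optional[TrainConfig] = None) -> TrainResult:
    """Optimize the model on slice-level samples; keep the best-accuracy epoch.

    Mini-batches are reshuffled every epoch under the config seed; a
    patient's slices may fall into different batches.  The checkpoint monitor
    is the image-level accuracy on the training set by default, or on a
    held-out stratified patient subset with ``monitor="validation"`` (the
    held-out patients are then excluded from the gradient updates).  Ties go
    to the earliest epoch.  On NaN loss the run aborts and the last good
    checkpoint is returned.
    """
    config = config or TrainConfig()
    if train_set.n == 0:
        raise ValueError("empty training set")
    pos_frac = float(np.mean(train_set.y))
    if not 0.4 <= pos_frac <= 0.6:
        import warnings
        warnings.warn(f"training set is label-imbalanced (positive fraction {pos_frac:.2f})")
    if config.monitor == "validation":
        fit_set, monitor_set = _validation_split(train_set, config.val_fraction,
                                                 config.seed + 2)
    elif config.monitor == "train":
        fit_set, monitor_set = train_set, None
    else:
        raise ValueError(f"unknown monitor {config.monitor!r}")
    rng = np.random.default_rng(config.seed)
    dropout_rng = np.random.default_rng(config.seed + 1) if config.dropout > 0 else None
    adam = Adam(model.params, lr=config.lr, betas=config.betas, eps=config.eps,
                weight_decay=config.weight_decay, amsgrad=config.amsgrad)
    best = TrainResult(best_params=model.copy_params(), best_epoch=0, best_accuracy=-1.0)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(fit_set.n)
        losses = []
        for start in range(0, fit_set.n, config.batch_size):
            rows = order[start:start + config.batch_size]
            loss, grads, _ = model.loss_and_grads(
                fit_set.batch(rows), fit_set.y[rows], loss_mode=config.loss_mode,
                dropout=config.dropout, dropout_rng=dropout_rng)
            if not np.isfinite(loss):
                best.diverged = True
                model.params = best.best_params
                return best
            adam.step(model.params, grads)
            losses.append(loss)
        train_acc = image_accuracy(model, fit_set, batch_size=max(64, config.batch_size))
        record = {"epoch": epoch, "loss": float(np.mean(losses)),
                  "train_accuracy": train_acc}
        if monitor_set is not None:
            monitor_acc = image_accuracy(model, monitor_set,
                                         batch_size=max(64, config.batch_size))
            record["val_accuracy"] = monitor_acc
        else:
            monitor_acc = train_acc
        best.history.append(record)
        if monitor_acc > best.best_accuracy:
            best.best_accuracy = monitor_acc
            best.best_epoch = epoch
            best.best_params = model.copy_params()
    model.params = best.best_params
    return best
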
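"""Loss, data splitting, SGD with step-decay schedule, and the training loop.

The loss is per-sample binary cross entropy

    L = -[y log(yhat) + (1 - y) log(1 - yhat)],

equivalently -log P(y|x) with P(y|x) = yhat^y (1 - yhat)^(1-y); batch loss
is the mean over samples.  Optimization is minibatch SGD with momentum;
the learning rate starts at 0.1 and is multiplied by 0.1 when training
reaches half and again at three-quarters of the epoch budget.  Data are
shuffled once and split 6:2:2 into train/validation/test.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn.model import AFNet, sigmoid
from .preprocess import Segment

__all__ = [
    "TrainConfig",
    "SplitIndices",
    "TrainHistory",
    "cross_entropy",
    "split_dataset",
    "lr_at_epoch",
    "SGD",
    "train",
]

_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 0.1
    decay_factor: float = 0.1
    milestone_fractions: tuple[float, ...] = (0.5, 0.75)
    epochs: int = 100
    batch_size: int = 64
    momentum: float = 0.9
    split_ratio: tuple[float, float, float] = (0.6, 0.2, 0.2)
    stratified: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError(f"lr0 must be positive, got {self.lr0}")
        if not 0 < self.decay_factor < 1:
            raise ValueError(f"decay_factor must lie in (0, 1), got {self.decay_factor}")
        if any(not 0 < f < 1 for f in self.milestone_fractions):
            raise ValueError("milestone fractions must lie strictly inside (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if any(r <= 0 for r in self.split_ratio) or abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError("split_ratio entries must be positive and sum to 1")


@dataclass
class SplitIndices:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "val_loss", "train_acc", "val_acc", "lr"])
            for e in range(len(self.train_loss)):
                writer.writerow([e, self.train_loss[e], self.val_loss[e],
                                 self.train_acc[e], self.val_acc[e], self.lr[e]])
        return path


def cross_entropy(y, yhat) -> float:
    """Mean binary cross entropy; predictions are clamped to [eps, 1-eps]."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    yhat = np.atleast_1d(np.asarray(yhat, dtype=float))
    if y.shape != yhat.shape:
        raise ValueError(f"label/prediction shape mismatch: {y.shape} vs {yhat.shape}")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be 0 or 1")
    p = np.clip(yhat, _EPS, 1 - _EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def split_dataset(n: int, ratio=(0.6, 0.2, 0.2), seed: int = 0,
                  labels=None, stratified: bool = False) -> SplitIndices:
    """Shuffle 0..n-1 by seed and cut floor(r0*n) / floor(r1*n) / remainder.

    With ``stratified`` the same rule is applied within each label value, so
    the class ratio is preserved per split.
    """
    if n < 5:
        raise ValueError(f"need n >= 5 to split 6:2:2, got {n}")
    rng = np.random.default_rng(seed)
    if stratified:
        if labels is None:
            raise ValueError("stratified split requires labels")
        labels = np.asarray(labels)
        parts = [[], [], []]
        for value in np.unique(labels):
            idx = np.flatnonzero(labels == value)
            rng.shuffle(idx)
            m = idx.size
            n_tr, n_va = int(np.floor(ratio[0] * m)), int(np.floor(ratio[1] * m))
            parts[0].append(idx[:n_tr])
            parts[1].append(idx[n_tr : n_tr + n_va])
            parts[2].append(idx[n_tr + n_va :])
        return SplitIndices(*(np.sort(np.concatenate(p)) for p in parts))
    perm = rng.permutation(n)
    n_train = int(np.floor(ratio[0] * n))
    n_val = int(np.floor(ratio[1] * n))
    return SplitIndices(perm[:n_train], perm[n_train : n_train + n_val],
                        perm[n_train + n_val :])


def lr_at_epoch(e: int, config: TrainConfig) -> float:
    """lr0 * decay^(milestones passed); milestones at floor(f * epochs)."""
    if not 0 <= e < config.epochs:
        raise ValueError(f"epoch {e} outside [0, {config.epochs})")
    passed = sum(1 for f in config.milestone_fractions
                 if e >= int(np.floor(f * config.epochs)))
    return config.lr0 * config.decay_factor**passed


class SGD:
    """Minibatch stochastic gradient descent with classical momentum."""

    def __init__(self, model: AFNet, momentum: float = 0.9) -> None:
        self.model = model
        self.momentum = momentum
        self.velocity = {
            name: np.zeros_like(leaf.params[key])
            for name, leaf, key in model.named_parameters()
        }

    def step(self, lr: float) -> None:
        for name, leaf, key in self.model.named_parameters():
            v = self.velocity[name]
            v *= self.momentum
            v -= lr * leaf.grads[key]
            leaf.params[key] += v.astype(leaf.params[key].dtype)


def _segments_to_arrays(segments: list[Segment]):
    x = np.stack([s.values for s in segments]).astype(np.float32)
    y = np.array([s.label.binary_label for s in segments], dtype=float)
    return x, y


def _evaluate(model: AFNet, x: np.ndarray, y: np.ndarray, batch_size: int):
    model.eval()
    probs = np.concatenate([
        model.predict_proba(x[i : i + batch_size])
        for i in range(0, len(x), batch_size)
    ])
    loss = cross_entropy(y, probs)
    acc = float(np.mean((probs >= 0.5) == (y == 1)))
    model.train()
    return loss, acc, probs


def train(
    model: AFNet,
    segments: list[Segment],
    config: TrainConfig,
    split: SplitIndices | None = None,
    verbose: bool = False,
) -> tuple[AFNet, TrainHistory, SplitIndices]:
    """Train on the 6:2:2 split of ``segments``; returns model, history, split.

    Fully reproducible: batching order is driven by ``config.seed`` and all
    numerics are single-threaded deterministic numpy.
    """
    x, y = _segments_to_arrays(segments)
    if split is None:
        labels = y if config.stratified else None
        split = split_dataset(len(segments), config.split_ratio, config.seed,
                              labels=labels, stratified=config.stratified)
    x_tr, y_tr = x[split.train], y[split.train]
    x_va, y_va = x[split.val], y[split.val]
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training split contains a single class; cannot fit a detector")

    rng = np.random.default_rng(config.seed + 1)
    opt = SGD(model, momentum=config.momentum)
    history = TrainHistory()
    model.train()
    for epoch in range(config.epochs):
        lr = lr_at_epoch(epoch, config)
        order = rng.permutation(len(x_tr))
        epoch_losses = []
        n_correct = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            model.zero_grad()
            logits = model.forward_logits(xb)
            probs = np.clip(sigmoid(logits), _EPS, 1 - _EPS)
            loss = cross_entropy(yb, probs)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or inspect the input data"
                )
            dlogits = ((probs - yb) / len(yb)).astype(np.float32)
            model.backward(dlogits)
            opt.step(lr)
            epoch_losses.append(loss * len(yb))
            n_correct += int(np.sum((probs >= 0.5) == (yb == 1)))
        # train metrics from the minibatch passes themselves (running estimate)
        va_loss, va_acc, _ = _evaluate(model, x_va, y_va, config.batch_size)
        history.train_loss.append(float(np.sum(epoch_losses) / len(x_tr)))
        history.val_loss.append(va_loss)
        history.train_acc.append(n_correct / len(x_tr))
        history.val_acc.append(va_acc)
        history.lr.append(lr)
        if verbose:
            print(f"epoch {epoch:3d}  lr {lr:g}  train_loss {history.train_loss[-1]:.4f} "
                  f"val_loss {va_loss:.4f}  train_acc {history.train_acc[-1]:.3f}  "
                  f"val_acc {va_acc:.3f}")
    return model, history, split
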
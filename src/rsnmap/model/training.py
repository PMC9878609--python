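"""Training loop: Adam, class-weighted deep-supervision loss, early stopping.

Training stops when the held-out accuracy has not strictly improved for
``patience`` consecutive validations (or at ``max_epochs``), and the
parameters from the best validation are restored.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ..similarity import TrainingSet
from .layers import add as _add
from .layers import weighted_cross_entropy
from .network import DenseResNet3D


class DivergenceError(RuntimeError):
    """Loss became non-finite during training."""


@dataclass(frozen=True)
class TrainSchedule:
    max_epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 3e-3
    weight_decay: float = 0.0  # decoupled L2 shrinkage per step
    validation_interval: int = 1  # epochs between validations
    patience: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1 or self.validation_interval < 1:
            raise ValueError("patience and validation_interval must be >= 1")


@dataclass
class TrainedModel:
    model: DenseResNet3D
    schedule: TrainSchedule
    history: list[dict] = field(default_factory=list)
    best_validation: int = -1  # index into history of the restored checkpoint

    @property
    def config(self):
        return self.model.config

    def predict_sample(self, sample) -> np.ndarray:
        """Final-head softmax vector for one similarity sample."""
        x = np.moveaxis(sample.channels, 0, -1)[None]  # (1, X, Y, Z, 2)
        return self.model.predict_proba(x)[0]

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)


def should_stop(val_accuracies: list[float], patience: int) -> bool:
    """Early-stopping rule: stop once ``patience`` consecutive validations have
    failed to strictly improve on the running best."""
    if len(val_accuracies) <= patience:
        return False
    best = val_accuracies[0]
    stale = 0
    for acc in val_accuracies[1:]:
        if acc > best:
            best = acc
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                return True
    return False


class Adam:
    """Adam with optional decoupled weight decay (AdamW-style)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            step = self.lr * mh / (np.sqrt(vh) + self.eps)
            if self.weight_decay:
                step = step + self.lr * self.weight_decay * p.data
            p.data -= step.astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def recalibrate_batchnorm(model: DenseResNet3D, x_cal: np.ndarray) -> None:
    """Replace batch-norm running statistics with population statistics.

    One forward pass over a representative calibration batch with momentum
    forced to 1 makes every layer's stored statistics exactly the statistics
    of its input *under those same statistics upstream*, removing the drift
    that accumulates when running averages trail fast-moving weights.
    """
    bns = model.batchnorms()
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 1.0
    try:
        model.forward(x_cal, training=True)
    finally:
        for bn, mom in zip(bns, saved):
            bn.momentum = mom


def _stack(samples, indices) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([np.moveaxis(samples[i].channels, 0, -1) for i in indices])
    y = np.array([samples[i].label for i in indices], dtype=np.intp)
    return x, y


def evaluate_accuracy(model: DenseResNet3D | TrainedModel, samples, labels) -> float:
    """Fraction of samples whose final-head argmax equals the label."""
    if isinstance(model, TrainedModel):
        model = model.model
    if len(samples) != len(labels):
        raise ValueError("samples and labels must have equal length")
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    x = np.stack([np.moveaxis(s.channels, 0, -1) for s in samples])
    pred = model.predict_proba(x).argmax(axis=1)
    return float((pred == np.asarray(labels)).mean())


def train_model(
    model: DenseResNet3D,
    tset: TrainingSet,
    sched: TrainSchedule = TrainSchedule(),
    verbose: bool = False,
) -> TrainedModel:
    """Train with class-weighted cross entropy summed over all heads.

    Fully reproducible given ``sched.rng_seed``; returns the model restored to
    its best-validation checkpoint together with the training history.
    """
    rng = np.random.default_rng(sched.rng_seed)
    train_idx = tset.indices("train")
    val_idx = tset.indices("val")
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("both train and validation splits must be populated")
    x_val, y_val = _stack(tset.samples, val_idx)
    weights = np.asarray(tset.class_weights, dtype=float)
    # fixed, evenly spaced calibration subset of the training split
    cal_idx = train_idx[np.linspace(0, len(train_idx) - 1, min(128, len(train_idx))).astype(int)]
    x_cal, _ = _stack(tset.samples, cal_idx)

    opt = Adam(model.parameters(), lr=sched.learning_rate, weight_decay=sched.weight_decay)
    history: list[dict] = []
    val_accs: list[float] = []
    best_state: dict | None = None
    best_idx = -1

    for epoch in range(sched.max_epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        n_batches = 0
        for i in range(0, len(order), sched.batch_size):
            xb, yb = _stack(tset.samples, order[i : i + sched.batch_size])
            opt.zero_grad()
            logits = model.forward(xb, training=True, rng=rng)
            loss = weighted_cross_entropy(logits[0], yb, weights)
            for lg in logits[1:]:
                loss = _add(loss, weighted_cross_entropy(lg, yb, weights))
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1

        if (epoch + 1) % sched.validation_interval == 0:
            recalibrate_batchnorm(model, x_cal)
            p_val = model.predict_proba(x_val)
            val_acc = float((p_val.argmax(axis=1) == y_val).mean())
            lp = np.log(np.maximum(p_val[np.arange(len(y_val)), y_val], 1e-30))
            val_loss = float(-(weights[y_val] * lp).sum() / weights[y_val].sum())
            val_accs.append(val_acc)
            history.append(
                {
                    "epoch": epoch + 1,
                    "train_loss": epoch_loss / max(n_batches, 1),
                    "val_acc": val_acc,
                    "val_loss": val_loss,
                }
            )
            if verbose:
                print(f"epoch {epoch + 1}: train_loss={epoch_loss / n_batches:.4f} val_acc={val_acc:.4f}")
            # best checkpoint: highest accuracy, ties broken by validation loss
            # (later, better-converged checkpoints win among equal accuracies)
            if (
                best_idx < 0
                or val_acc > val_accs[best_idx]
                or (
                    val_acc == val_accs[best_idx]
                    and val_loss < history[best_idx]["val_loss"]
                )
            ):
                best_idx = len(val_accs) - 1
                best_state = copy.deepcopy(model.state_dict())
            if should_stop(val_accs, sched.patience):
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainedModel(model=model, schedule=sched, history=history, best_validation=best_idx)
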
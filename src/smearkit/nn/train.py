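"""Training loop with the pipeline's regularisation policy.

The policy mirrors the segmentation model's published recipe and is reused
(with a categorical loss) by the classifier: Adam (lr 1e-3, beta1 0.9,
beta2 0.999, eps 1e-7), batch size 16, early stopping on validation loss
with best-weight restore, and reduce-LR-on-plateau (factor 0.5, patience
5, floor 1e-5).  L2 kernel regularisation lives on the layers themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Sequential
from .optim import Adam

_EPS = 1e-7


def bce_loss(p: np.ndarray, t: np.ndarray) -> float:
    """Binary cross-entropy, mean over every pixel/unit."""
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))


def bce_grad_logits(p: np.ndarray, t: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d(logits) for a sigmoid head (fused derivative)."""
    return ((p - t) / p.size).astype(np.float32)


def cce_loss(p: np.ndarray, t_onehot: np.ndarray) -> float:
    """Categorical cross-entropy, mean over samples."""
    p = np.clip(p, _EPS, 1.0)
    return float(-np.mean(np.sum(t_onehot * np.log(p), axis=-1)))


def cce_grad_logits(p: np.ndarray, t_onehot: np.ndarray) -> np.ndarray:
    """d(mean CCE)/d(logits) for a softmax head (fused derivative)."""
    return ((p - t_onehot) / p.shape[0]).astype(np.float32)


_LOSSES = {"bce": (bce_loss, bce_grad_logits), "cce": (cce_loss, cce_grad_logits)}


@dataclass
class TrainingPolicy:
    """Optimisation and regularisation settings (units: lr is unitless step
    size on float32 weights; patience values are epochs)."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    batch_size: int = 16
    max_epochs: int = 50
    loss: str = "bce"
    early_stopping_patience: int = 10
    restore_best_weights: bool = True
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    lr_floor: float = 1e-5
    l2: float = 1e-4  # consumed at model build time (kernel penalty)

    def __post_init__(self):
        if self.loss not in _LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.lr < self.lr_floor:
            raise ValueError("initial learning rate below the plateau floor")


@dataclass
class History:
    """Per-epoch training record (one list entry per completed epoch)."""

    loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    metrics: dict[str, list[float]] = field(default_factory=dict)
    best_epoch: int = -1
    stopped_epoch: int = -1

    def __len__(self) -> int:
        return len(self.loss)


def _forward_in_batches(model, x, batch_size):
    outs = [model.forward(x[i : i + batch_size], training=False) for i in range(0, len(x), batch_size)]
    return np.concatenate(outs, axis=0)


def fit(
    model: Sequential,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    policy: TrainingPolicy,
    seed: int = 0,
    metric_fns: dict | None = None,
    stop_metric: str | None = None,
    stop_value: float | None = None,
    verbose: bool = False,
) -> History:
    """Train ``model`` in place and return the epoch history.

    ``metric_fns`` maps names to ``f(y_true, y_pred) -> float`` evaluated on
    the validation split each epoch.  ``stop_metric``/``stop_value`` allow a
    convergence exit once a monitored validation metric reaches a level
    (used by desk-scale experiments to avoid training past convergence).
    Early stopping and the LR schedule monitor validation loss.
    """
    if len(x_train) == 0:
        raise ValueError("empty training set")
    if len(x_train) != len(y_train):
        raise ValueError("inputs and targets are misaligned")
    loss_fn, grad_fn = _LOSSES[policy.loss]
    rng = np.random.default_rng(seed)
    opt = Adam(model.layers if hasattr(model, "layers") else model.trainable(),
               lr=policy.lr, beta1=policy.beta1, beta2=policy.beta2, eps=policy.eps)
    hist = History()
    best_val = np.inf
    best_weights = None
    since_improve = 0
    since_plateau = 0
    n = len(x_train)
    for epoch in range(policy.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, policy.batch_size):
            idx = order[start : start + policy.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            p = model.forward(xb, training=True)
            epoch_loss += loss_fn(p, yb)
            n_batches += 1
            model.backward(grad_fn(p, yb))
            opt.step()
        p_val = _forward_in_batches(model, x_val, policy.batch_size)
        val_loss = loss_fn(p_val, y_val)
        hist.loss.append(epoch_loss / max(n_batches, 1))
        hist.val_loss.append(val_loss)
        hist.lr.append(opt.lr)
        if metric_fns:
            for name, fn in metric_fns.items():
                hist.metrics.setdefault(name, []).append(float(fn(y_val, p_val)))
        if verbose:
            extras = {k: v[-1] for k, v in hist.metrics.items()}
            print(f"epoch {epoch + 1}: loss={hist.loss[-1]:.4f} val_loss={val_loss:.4f} "
                  f"lr={opt.lr:.2e} {extras}")
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            hist.best_epoch = epoch
            since_improve = 0
            since_plateau = 0
            if policy.restore_best_weights:
                best_weights = model.get_weights()
        else:
            since_improve += 1
            since_plateau += 1
        if since_plateau > policy.plateau_patience:
            opt.lr = max(opt.lr * policy.plateau_factor, policy.lr_floor)
            since_plateau = 0
        if (
            stop_metric is not None
            and stop_value is not None
            and hist.metrics.get(stop_metric)
            and hist.metrics[stop_metric][-1] >= stop_value
        ):
            hist.stopped_epoch = epoch
            best_weights = None  # convergence exit keeps the current weights
            break
        if since_improve > policy.early_stopping_patience:
            hist.stopped_epoch = epoch
            break
    if policy.restore_best_weights and best_weights is not None:
        model.set_weights(best_weights)
    return hist
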
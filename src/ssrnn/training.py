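"""Cross-entropy loss, plain SGD and the mini-batch training loop.

The published recipe is deliberately simple: stochastic gradient descent
at learning rate 0.01 for 50 epochs, cross-entropy loss. No momentum,
weight decay, schedules or early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, clip_min, log, zero_grads

__all__ = ["TrainConfig", "cross_entropy", "sgd_step", "train", "one_hot"]

PROB_FLOOR = 1e-12  # probabilities are clamped here before the log


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be >= 1")


def one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if y.min() < 0 or y.max() >= n_classes:
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    out = np.zeros((y.size, n_classes))
    out[np.arange(y.size), y] = 1.0
    return out


def cross_entropy(y_true, y_prob, reduction: str = "mean"):
    """Cross-entropy -sum_i y_i log(p_i), summed over classes.

    ``y_true`` is one-hot (batch, K) or (K,); ``y_prob`` are predicted
    probabilities, clamped at 1e-12 before the log. ``reduction`` controls
    batch aggregation: 'mean' for a per-sample average (reporting),
    'sum' for the plain summed loss that training minimises. Returns a
    float when both inputs are plain arrays, a differentiable Tensor
    otherwise.
    """
    if reduction not in ("mean", "sum"):
        raise ValueError(f"unknown reduction {reduction!r}")
    plain = not isinstance(y_true, Tensor) and not isinstance(y_prob, Tensor)
    y, p = as_tensor(y_true), as_tensor(y_prob)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {p.shape}")
    yv = y.value
    if not np.allclose(yv.sum(axis=-1), 1.0) or np.any((yv != 0) & (yv != 1)):
        raise ValueError("y_true must be one-hot")
    ll = y * log(clip_min(p, PROB_FLOOR))
    if p.ndim > 1:
        per_sample = ll.sum(axis=-1)
        loss = -(per_sample.mean() if reduction == "mean" else per_sample.sum())
    else:
        loss = -ll.sum()
    return float(loss.value) if plain else loss


def sgd_step(params, gradients=None, lr: float = 0.01):
    """p <- p - lr * g, elementwise, for each parameter.

    With ``gradients=None`` the Tensors' own ``.grad`` fields are used and
    updated in place; otherwise plain arrays are combined functionally and
    the updated arrays returned.
    """
    if gradients is None:
        for p in params:
            if p.grad is None:
                continue
            if not np.all(np.isfinite(p.grad)):
                raise FloatingPointError("non-finite gradient encountered")
            p.value -= lr * p.grad
        return params
    out = []
    for p, g in zip(params, gradients, strict=True):
        p, g = np.asarray(p, dtype=float), np.asarray(g, dtype=float)
        if p.shape != g.shape:
            raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient encountered")
        out.append(p - lr * g)
    return out


def train(net, X, y, cfg: TrainConfig) -> list[float]:
    """Train ``net`` in place; returns the mean train loss per epoch.

    Deterministic for a fixed ``cfg.seed``: both the initial shuffling and
    every epoch's batch order derive from it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n == 0:
        raise ValueError("empty dataset")
    K = net.config.n_classes
    Y = one_hot(y, K)
    rng = np.random.default_rng(cfg.seed)
    params = net.parameters()
    curve: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        total, seen = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs = net.forward(X[idx])
            # the optimised objective is the summed cross-entropy; the
            # recorded curve is its per-sample mean
            loss = cross_entropy(Tensor(Y[idx]), probs, reduction="sum")
            if not np.isfinite(loss.value):
                raise FloatingPointError(
                    f"non-finite loss in epoch {epoch}, batch starting at {start} "
                    "(exploding gradients?)"
                )
            zero_grads(params)
            loss.backward()
            sgd_step(params, lr=cfg.learning_rate)
            total += float(loss.value)
            seen += len(idx)
        curve.append(total / seen)
    return curve
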
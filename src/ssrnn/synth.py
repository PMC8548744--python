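"""Synthetic benchmarks with controllable long-range dependency structure.

Two generators:

* ``gen_delayed_recall`` — sequences of one-hot symbols (optionally with
  Gaussian noise) whose label is the symbol emitted a fixed lag before the
  sequence end. The task isolates long-term-memory capability: a model
  must carry the symbol at position T - d (1-based) to the readout at
  position T. At zero noise the Bayes-optimal accuracy is 1.
* ``gen_tabular`` — a binary-label multi-feature table (16 features by
  default, emulating a diabetes-questionnaire style dataset) drawn from
  two class-conditional Gaussians, with configurable class separation and
  injected missing values and outlier records for exercising the
  preprocessing path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RecallTaskSpec", "TabularTaskSpec", "gen_delayed_recall", "gen_tabular"]


@dataclass(frozen=True)
class RecallTaskSpec:
    n: int = 2500
    length: int = 20
    vocab: int = 4
    lag: int = 3  # label = symbol this many steps before the sequence end
    noise: float = 0.0  # std of isotropic Gaussian added to the one-hot codes
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.lag < self.length:
            raise ValueError(f"lag must satisfy 1 <= lag < length, got {self.lag}")
        if self.vocab < 2:
            raise ValueError("vocabulary size must be >= 2")
        if self.noise < 0:
            raise ValueError("noise std must be nonnegative")


def gen_delayed_recall(spec: RecallTaskSpec) -> tuple[np.ndarray, np.ndarray]:
    """Returns (X, y): X is (n, length, vocab) one-hot + noise, y is the
    symbol at 1-based position length - lag."""
    rng = np.random.default_rng(spec.seed)
    symbols = rng.integers(0, spec.vocab, size=(spec.n, spec.length))
    X = np.zeros((spec.n, spec.length, spec.vocab))
    rows = np.arange(spec.n)[:, None]
    cols = np.arange(spec.length)[None, :]
    X[rows, cols, symbols] = 1.0
    if spec.noise > 0:
        X += rng.normal(0.0, spec.noise, size=X.shape)
    y = symbols[:, spec.length - spec.lag - 1].copy()
    return X, y


@dataclass(frozen=True)
class TabularTaskSpec:
    n: int = 520
    n_features: int = 16
    separation: float = 3.0  # Mahalanobis distance between the class means
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    n_binary: int = 0  # how many features are thresholded to 0/1
    seed: int = 0

    def __post_init__(self):
        if self.n < 4:
            raise ValueError("need at least 4 records")
        for r in (self.missing_rate, self.outlier_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must be in [0, 1)")
        if not 0 <= self.n_binary <= self.n_features:
            raise ValueError("n_binary out of range")


@dataclass(frozen=True)
class TabularTruth:
    """Ground truth kept for recovery tests."""

    clean: pd.DataFrame  # values before missing/outlier injection
    outlier_mask: np.ndarray  # True for records turned into outliers
    missing_mask: np.ndarray  # True where a cell was blanked


def gen_tabular(spec: TabularTaskSpec) -> tuple[pd.DataFrame, TabularTruth]:
    """Two-Gaussian binary classification table with labels balanced
    within one record; the last column 'label' is 0/1."""
    rng = np.random.default_rng(spec.seed)
    m = spec.n_features
    # class means +-delta/2 per feature give total separation `separation`
    delta = spec.separation / np.sqrt(m)
    n1 = spec.n // 2
    y = np.concatenate([np.zeros(spec.n - n1, dtype=int), np.ones(n1, dtype=int)])
    rng.shuffle(y)
    X = rng.normal(0.0, 1.0, size=(spec.n, m)) + np.where(y[:, None] == 1, delta / 2, -delta / 2)
    if spec.n_binary:
        X[:, m - spec.n_binary :] = (X[:, m - spec.n_binary :] > 0).astype(float)
    cols = [f"f{i}" for i in range(m)]
    clean = pd.DataFrame(X, columns=cols)
    clean["label"] = y

    table = clean.copy()
    out_mask = np.zeros(spec.n, dtype=bool)
    if spec.outlier_rate > 0:
        k = int(round(spec.outlier_rate * spec.n))
        which = rng.choice(spec.n, size=k, replace=False)
        out_mask[which] = True
        # an outlier record sits far in the tails of every numeric feature
        n_num = m - spec.n_binary
        table.iloc[which, :n_num] = 8.0 * rng.choice([-1.0, 1.0], size=(k, n_num))
    miss_mask = np.zeros((spec.n, m), dtype=bool)
    if spec.missing_rate > 0:
        miss_mask = rng.random((spec.n, m)) < spec.missing_rate
        vals = table[cols].to_numpy(dtype=float)
        vals[miss_mask] = np.nan
        table[cols] = vals
    return table, TabularTruth(clean=clean, outlier_mask=out_mask, missing_mask=miss_mask)
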
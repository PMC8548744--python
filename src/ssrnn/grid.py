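"""The comparison grid: plain LSTM plus every (variant, skip) combination.

The default grid is the baseline plus 6 variants x 4 skip orders
(2, 3, 4, 5) = 25 configurations, each trained and evaluated on the same
train/test split with a per-configuration seed derived stably from the
base seed.
"""

from __future__ import annotations

import zlib
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classifier import SkipLSTMClassifier
from .data import standard_split
from .metrics import confusion, metrics
from .training import TrainConfig

__all__ = ["DEFAULT_SKIPS", "DEFAULT_VARIANTS", "grid_configurations", "run_grid"]

DEFAULT_VARIANTS = ("A", "B", "C", "D", "E", "F")
DEFAULT_SKIPS = (2, 3, 4, 5)


def grid_configurations(
    variants: Sequence[str] = DEFAULT_VARIANTS,
    skips: Sequence[int] = DEFAULT_SKIPS,
) -> list[tuple[str, Optional[int]]]:
    """Baseline first, then every (variant, skip) pair."""
    out: list[tuple[str, Optional[int]]] = [("none", None)]
    for v in variants:
        for s in skips:
            out.append((v, int(s)))
    return out


def config_seed(base_seed: int, variant: str, skip: Optional[int]) -> int:
    """Stable per-configuration seed: base + CRC32 of the config name."""
    tag = f"{variant}-{skip}"
    return (int(base_seed) + zlib.crc32(tag.encode())) % (2**31)


def run_grid(
    X,
    y,
    variants: Sequence[str] = DEFAULT_VARIANTS,
    skips: Sequence[int] = DEFAULT_SKIPS,
    cfg: TrainConfig = None,
    test_fraction: float = 0.2,
    hidden_dims: tuple = (18, 8, 5),
    averaging: str = "weighted",
    log: Optional[callable] = None,
) -> pd.DataFrame:
    """Train and evaluate every grid configuration on a shared split.

    Returns one row per configuration with the final loss, the evaluation
    metrics and the per-epoch loss curve. A configuration that raises is
    recorded with status 'failed' and the grid continues.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    split = standard_split(len(y), fraction=1.0 - test_fraction, seed=cfg.seed, labels=y)
    Xtr, ytr = X[split.train], y[split.train]
    Xte, yte = X[split.test], y[split.test]
    K = len(np.unique(y))
    rows = []
    for variant, skip in grid_configurations(variants, skips):
        seed = config_seed(cfg.seed, variant, skip)
        name = "baseline" if variant == "none" else f"{variant}-{skip}"
        if log:
            log(f"grid: training {name} (seed {seed})")
        row = {"variant": variant, "skip": skip, "seed": seed, "status": "ok"}
        try:
            clf = SkipLSTMClassifier(
                variant=variant,
                skip=skip or 3,
                hidden_dims=hidden_dims,
                learning_rate=cfg.learning_rate,
                epochs=cfg.epochs,
                batch_size=cfg.batch_size,
                shuffle=cfg.shuffle,
                random_state=seed,
            ).fit(Xtr, ytr)
            pred = clf.predict(Xte)
            enc = {c: i for i, c in enumerate(clf.classes_)}
            rep = metrics(
                confusion([enc[v] for v in yte], [enc[v] for v in pred], K),
                mode=averaging,
            )
            row.update(
                final_loss=clf.loss_curve_[-1],
                accuracy=rep.accuracy,
                precision=rep.precision,
                recall=rep.recall,
                f1=rep.f1,
                loss_curve=clf.loss_curve_,
            )
        except Exception as exc:  # noqa: BLE001 - a failed run must not kill the grid
            row.update(
                status="failed",
                error=f"{type(exc).__name__}: {exc}",
                final_loss=np.nan,
                accuracy=np.nan,
                precision=np.nan,
                recall=np.nan,
                f1=np.nan,
                loss_curve=None,
            )
        rows.append(row)
    return pd.DataFrame(rows)
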
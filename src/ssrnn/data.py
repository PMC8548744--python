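"""Preprocessing, the 80/20 standard split, and delimited-file I/O.

Conventions: CSV with '.' decimals, '?' or an empty field marking a
missing value; the last column of a data file is the integer class label.
Mean imputation for numeric features, mode imputation for binary ones;
outlier records are dropped by a per-feature z-score rule.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "SplitIndices",
    "impute_missing",
    "drop_outliers",
    "standard_split",
    "round_half_up",
    "load_sequence_csv",
    "save_sequence_csv",
    "load_tabular_csv",
    "save_tabular_csv",
]

MISSING_TOKENS = {"?", ""}


# -----------------------------------------------------------------------------
# preprocessing
# -----------------------------------------------------------------------------
def _is_binary(col: pd.Series) -> bool:
    vals = set(col.dropna().unique())
    return vals <= {0, 1, 0.0, 1.0}


def impute_missing(table: pd.DataFrame, label_col: Optional[str] = None) -> pd.DataFrame:
    """Fill missing numeric entries with the column mean over observed
    values; binary (0/1) columns use the column mode instead."""
    out = table.copy()
    cols = [c for c in out.columns if c != label_col]
    for c in cols:
        col = out[c]
        if not col.isna().any():
            continue
        observed = col.dropna()
        if observed.empty:
            raise ValueError(f"column {c!r} is entirely missing; cannot impute")
        if _is_binary(col):
            fill = observed.mode().iloc[0]
        else:
            fill = observed.mean()
        out[c] = col.fillna(fill)
    return out


def drop_outliers(
    table: pd.DataFrame,
    z_max: float = 3.0,
    label_col: Optional[str] = None,
) -> tuple[pd.DataFrame, int]:
    """Remove records with any numeric feature beyond ``z_max`` standard
    deviations from its column mean. Zero-variance columns never flag.

    The rule is applied to convergence (removals shift the column
    statistics, so passes repeat until no record exceeds the threshold),
    which makes the filter idempotent. Returns (filtered table, number
    removed)."""
    if table.isna().any().any():
        raise ValueError("impute before dropping outliers")
    cols = [c for c in table.columns if c != label_col and not _is_binary(table[c])]
    out = table.copy()
    if not cols or not math.isfinite(z_max):
        return out, 0
    removed = 0
    while len(out) > 1:
        X = out[cols].to_numpy(dtype=float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = np.inf  # zero-variance columns never flag outliers
        z = np.abs((X - mu) / sd)
        keep = (z <= z_max).all(axis=1)
        if keep.all():
            break
        removed += int((~keep).sum())
        out = out.loc[keep]
    return out.copy(), removed


# -----------------------------------------------------------------------------
# splitting
# -----------------------------------------------------------------------------
def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    test: np.ndarray
    fraction: float
    seed: int

    def __post_init__(self):
        both = np.concatenate([self.train, self.test])
        n = len(both)
        if not np.array_equal(np.sort(both), np.arange(n)):
            raise ValueError("train/test must partition 0..n-1")


def standard_split(
    n: int,
    fraction: float = 0.8,
    seed: int = 0,
    labels: Optional[Sequence] = None,
) -> SplitIndices:
    """Seeded shuffled split with |train| = round-half-up(fraction * n).

    With ``labels`` given the split is stratified by class (the exact
    train size is preserved).
    """
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_train = round_half_up(fraction * n)
    n_train = min(max(n_train, 1), n - 1)
    idx = np.arange(n)
    if labels is not None:
        tr, te = train_test_split(
            idx,
            train_size=n_train,
            random_state=seed % (2**32 - 1),
            shuffle=True,
            stratify=np.asarray(labels),
        )
    else:
        perm = np.random.default_rng(seed).permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
    return SplitIndices(np.asarray(tr), np.asarray(te), fraction, seed)


# -----------------------------------------------------------------------------
# sequence CSV (one sequence per row, last column = label)
# -----------------------------------------------------------------------------
def load_sequence_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read sequences; returns (X, y) with X of shape (n, T, d).

    A JSON sidecar ``<path>.json`` with keys ``length`` and ``features``
    declares the per-timestep feature width d (row-major flattening);
    without it d = 1.
    """
    path = Path(path)
    rows = []
    width = None
    with path.open(newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row:
                continue
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValueError(
                    f"{path.name}: ragged row {i} (got {len(row)} fields, expected {width})"
                )
            try:
                rows.append([float(v) for v in row])
            except ValueError as exc:
                raise ValueError(f"{path.name}: non-numeric entry in row {i}: {exc}") from exc
    if not rows:
        raise ValueError(f"{path.name}: empty file")
    data = np.asarray(rows)
    X_flat, y = data[:, :-1], data[:, -1]
    if not np.all(y == y.astype(int)):
        raise ValueError("labels must be integers")
    sidecar = path.with_name(path.name + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        T, d = int(meta["length"]), int(meta["features"])
        if T * d != X_flat.shape[1]:
            raise ValueError(
                f"sidecar declares {T}x{d}={T*d} values/row but file has {X_flat.shape[1]}"
            )
    else:
        T, d = X_flat.shape[1], 1
    return X_flat.reshape(len(rows), T, d), y.astype(int)


def save_sequence_csv(path, X: np.ndarray, y: np.ndarray) -> None:
    """Write (n, T, d) sequences row-major with the label appended; a JSON
    sidecar records the (length, features) shape."""
    path = Path(path)
    X = np.asarray(X)
    if X.ndim == 2:
        X = X[:, :, None]
    n, T, d = X.shape
    flat = X.reshape(n, T * d)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        for row, label in zip(flat, np.asarray(y, dtype=int)):
            w.writerow([repr(float(v)) for v in row] + [int(label)])
    path.with_name(path.name + ".json").write_text(
        json.dumps({"length": T, "features": d}) + "\n"
    )


# -----------------------------------------------------------------------------
# tabular CSV (features + label column)
# -----------------------------------------------------------------------------
def load_tabular_csv(path, schema: Optional[dict] = None,
                     label_col: Optional[str] = None) -> pd.DataFrame:
    """Read a feature table; '?' and empty fields become NaN.

    ``schema`` maps column name -> {category: integer code} for encoding
    categorical columns; an unknown category is a parse error naming the
    offending row.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        expected = None
        for i, row in enumerate(csv.reader(fh)):
            if not row:
                continue
            if expected is None:
                expected = len(row)
            elif len(row) != expected:
                raise ValueError(f"{path.name}: ragged row {i}")
    df = pd.read_csv(path, na_values=list(MISSING_TOKENS), keep_default_na=False,
                     skipinitialspace=True)
    if schema:
        for col, mapping in schema.items():
            known = df[col].isna() | df[col].astype(str).isin(mapping)
            if not known.all():
                bad = int(np.argmax(~known.to_numpy()))
                raise ValueError(
                    f"{path.name}: unknown category {df[col].iloc[bad]!r} "
                    f"in column {col!r}, row {bad}"
                )
            df[col] = df[col].map(lambda v: mapping.get(str(v)) if pd.notna(v) else np.nan)
    for c in df.columns:
        df[c] = pd.to_numeric(df[c])
    label = label_col or df.columns[-1]
    lab = df[label].dropna()
    if not (lab == lab.astype(int)).all():
        raise ValueError(f"label column {label!r} must be integer")
    return df


def save_tabular_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, na_rep="?")
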
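"""Independent brute-force oracles used to validate the implementation.

Everything here is written directly from the cell update equations using
per-gate NumPy arithmetic and explicit time loops — deliberately sharing
no code with the package's stacked, autodiff-backed implementation.
"""

from __future__ import annotations

import numpy as np

GATES = ("f", "i", "o", "g")


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def arrays_of(p):
    """Extract plain ndarrays from a CellParams."""
    out = {
        "W_h": {g: p.W_h[g].value.copy() for g in p.W_h},
        "W_x": {g: p.W_x[g].value.copy() for g in GATES},
        "b": {g: p.b[g].value.copy() for g in GATES},
    }
    if p.W_skip is not None:
        out["W_skip"] = {g: p.W_skip[g].value.copy() for g in GATES}
    if p.W_lag is not None:
        out["W_lag"] = {g: [w.value.copy() for w in p.W_lag[g]] for g in GATES}
    return out


def oracle_step(x, h_prev, c_prev, pa, extra=None, recur=None):
    """One LSTM update with optional per-gate pre-activation extras or a
    replacement recurrent term (dict gate -> vector)."""
    pre = {}
    for g in GATES:
        r = recur[g] if recur is not None else pa["W_h"][g] @ h_prev
        pre[g] = pa["W_x"][g] @ x + r + pa["b"][g]
        if extra is not None:
            pre[g] = pre[g] + extra[g]
    f, i, o = sigmoid(pre["f"]), sigmoid(pre["i"]), sigmoid(pre["o"])
    cand = np.tanh(pre["g"])
    c = f * c_prev + i * cand
    h = o * np.tanh(c)
    return h, c


def oracle_unroll(xs, variant, skip, pa):
    """Sequentially apply the variant update to a single (T, D) sequence.

    Returns (hs, cs) as lists of vectors, t = 1..T. History entries for
    t <= 0 are zero vectors.
    """
    T = len(xs)
    H = pa["b"]["f"].shape[0]
    if variant == "E":
        pa = dict(pa)
        pa["W_h"] = {g: pa["W_lag"][g][0] for g in GATES}
    hs, cs = [], []
    h, c = np.zeros(H), np.zeros(H)

    def hist(t, lag):  # h_{t-lag}, zeros when out of range
        return hs[t - lag - 1] if t - lag >= 1 else np.zeros(H)

    for t in range(1, T + 1):
        trigger = t > 1 and (t - 1) % skip == 0
        extra = None
        recur = None
        if variant == "B" and trigger:
            extra = {g: pa["W_skip"][g] @ hist(t, skip) for g in GATES}
        elif variant == "D":
            extra = {g: pa["W_skip"][g] @ hist(t, skip) for g in GATES}
        elif variant == "E" and trigger:
            recur = {
                g: sum(pa["W_lag"][g][l - 1] @ hist(t, l) for l in range(1, skip + 1))
                for g in GATES
            }
        h, c = oracle_step(xs[t - 1], h, c, pa, extra=extra, recur=recur)
        if variant == "A" and trigger:
            h = h + hist(t, skip)
        elif variant == "C":
            h = h + hist(t, skip)
        elif variant == "F" and trigger:
            h = h + sum(hist(t, s) for s in range(2, skip + 1))
        hs.append(h)
        cs.append(c)
    return hs, cs


def oracle_metrics(y_true, y_pred, n_classes, mode="weighted"):
    """Per-class counting metrics computed with explicit loops."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    n = len(y_true)
    acc = sum(t == p for t, p in zip(y_true, y_pred)) / n
    per = []
    for k in range(n_classes):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == k and p == k)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != k and p == k)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == k and p != k)
        support = sum(1 for t in y_true if t == k)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per.append((prec, rec, f1, support))
    if mode == "weighted":
        weights = [s / n for (_, _, _, s) in per]
    else:
        weights = [1.0 / n_classes] * n_classes
    precision = sum(w * p for w, (p, _, _, _) in zip(weights, per))
    recall = sum(w * r for w, (_, r, _, _) in zip(weights, per))
    f1 = sum(w * f for w, (_, _, f, _) in zip(weights, per))
    return acc, precision, recall, f1
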
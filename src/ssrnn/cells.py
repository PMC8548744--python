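"""Skip-augmented LSTM cells and baseline recurrent cells.

The strengthened-skip family injects the hidden state from ``skip``
timesteps in the past into the current recurrence, in six ways spanning
{discontinuous, continuous} x {direct addition to h, weighted injection
into the gate pre-activations}, plus two multi-lag forms:

=========  ==================================================================
variant A  at trigger steps t = 1 + i*skip, h_t = o*tanh(c) + h_{t-skip}
variant B  at trigger steps, every gate pre-activation gains
           W_skip @ h_{t-skip} in addition to the usual W_h @ h_{t-1}
variant C  h_t = o*tanh(c) + h_{t-skip} at EVERY step (zeros before t>skip)
variant D  weighted injection of variant B at EVERY step
variant E  at trigger steps the recurrent term is replaced by the multi-lag
           sum over l = 1..skip of W_l @ h_{t-l}; otherwise a standard step
           with W_1 as the recurrent weight
variant F  at trigger steps, h_t = o*tanh(c) + sum over s = 2..skip of
           h_{t-s}
=========  ==================================================================

The cell state c_t never receives skip information; only gates and h do.
Time is 1-based; states for t <= 0 are zero vectors. All step functions are
pure: they map (input, history, previous state, parameters) to a new state
and are differentiable through :mod:`ssrnn.autodiff`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, as_tensor, concat, sigmoid, tanh

__all__ = [
    "GATES",
    "VARIANTS",
    "SkipSpec",
    "CellParams",
    "CellState",
    "HistoryBuffer",
    "RNNParams",
    "GRUParams",
    "is_trigger",
    "lstm_step",
    "step_model_a",
    "step_model_b",
    "step_model_c",
    "step_model_d",
    "step_model_e",
    "step_model_f",
    "rnn_step",
    "gru_step",
    "unroll",
]

# gate order used for stacked pre-activations: three sigmoid gates, then the
# tanh candidate
GATES = ("f", "i", "o", "g")
VARIANTS = ("none", "A", "B", "C", "D", "E", "F")
_WEIGHTED_VARIANTS = frozenset({"B", "D"})
_LAG_VARIANTS = frozenset({"E"})


@dataclass(frozen=True)
class SkipSpec:
    """Which skip variant is active and at what lag (the *order*)."""

    variant: str = "none"
    skip: int = 3

    def __post_init__(self):
        v = self.variant
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}; expected one of {VARIANTS}")
        if v != "none" and self.skip < 2:
            raise ValueError(f"skip must be >= 2, got {self.skip}")

    @property
    def uses_skip_weights(self) -> bool:
        return self.variant in _WEIGHTED_VARIANTS

    @property
    def uses_lag_weights(self) -> bool:
        return self.variant in _LAG_VARIANTS


def is_trigger(t: int, skip: int) -> bool:
    """True iff t = 1 + i*skip for a positive integer i.

    Trigger steps are where the discontinuous variants (A, B, E, F) open
    their skip pathway; t = 1 is never a trigger.
    """
    if t < 1:
        raise ValueError(f"time index must be >= 1, got {t}")
    if skip < 2:
        raise ValueError(f"skip must be >= 2, got {skip}")
    return t > 1 and (t - 1) % skip == 0


def _uniform(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


@dataclass
class CellParams:
    """All weights of one (possibly skip-augmented) LSTM cell.

    Per gate g in {f, i, o, g(candidate)}: recurrent weight ``W_h[g]``
    (hidden x hidden), input weight ``W_x[g]`` (hidden x input) and bias
    ``b[g]``. Variants B/D additionally carry ``W_skip[g]``; variant E
    carries per-lag weights ``W_lag[g][l-1]`` for lags l = 1..skip, where
    the lag-1 matrix doubles as the recurrent weight (``W_h`` is then not
    allocated).
    """

    input_dim: int
    hidden_dim: int
    W_h: dict = field(default_factory=dict)
    W_x: dict = field(default_factory=dict)
    b: dict = field(default_factory=dict)
    W_skip: Optional[dict] = None
    W_lag: Optional[dict] = None

    @classmethod
    def init(
        cls,
        input_dim: int,
        hidden_dim: int,
        spec: SkipSpec = SkipSpec(),
        rng: np.random.Generator | int | None = 0,
    ) -> "CellParams":
        """Initialise uniformly in +-1/sqrt(hidden_dim), seeded."""
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        scale = 1.0 / np.sqrt(hidden_dim)
        p = cls(input_dim=input_dim, hidden_dim=hidden_dim)
        for g in GATES:
            if not spec.uses_lag_weights:
                p.W_h[g] = _uniform(rng, (hidden_dim, hidden_dim), scale)
            p.W_x[g] = _uniform(rng, (hidden_dim, input_dim), scale)
            p.b[g] = _uniform(rng, (hidden_dim,), scale)
        if spec.uses_skip_weights:
            p.W_skip = {g: _uniform(rng, (hidden_dim, hidden_dim), scale) for g in GATES}
        if spec.uses_lag_weights:
            p.W_lag = {
                g: [_uniform(rng, (hidden_dim, hidden_dim), scale) for _ in range(spec.skip)]
                for g in GATES
            }
        return p

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for g in GATES:
            if g in self.W_h:
                out[f"{prefix}{g}.W_h"] = self.W_h[g]
            out[f"{prefix}{g}.W_x"] = self.W_x[g]
            out[f"{prefix}{g}.b"] = self.b[g]
            if self.W_skip is not None:
                out[f"{prefix}{g}.W_skip"] = self.W_skip[g]
            if self.W_lag is not None:
                for l, w in enumerate(self.W_lag[g], start=1):
                    out[f"{prefix}{g}.W_lag{l}"] = w
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def validate(self, spec: SkipSpec) -> None:
        if spec.uses_skip_weights and self.W_skip is None:
            raise ValueError(f"variant {spec.variant} requires skip weights W_skip")
        if spec.uses_lag_weights:
            if self.W_lag is None:
                raise ValueError("variant E requires per-lag weights W_lag")
            for g in GATES:
                if len(self.W_lag[g]) != spec.skip:
                    raise ValueError(
                        f"variant E needs {spec.skip} lag matrices per gate, "
                        f"got {len(self.W_lag[g])} for gate {g!r}"
                    )

    # -- stacked views -------------------------------------------------------
    def stack(self, spec: SkipSpec = SkipSpec()) -> "_StackedCell":
        """Concatenate per-gate weights into single matmul-ready blocks."""
        self.validate(spec)
        if spec.uses_lag_weights:
            WhT = concat([self.W_lag[g][0] for g in GATES], axis=0)
        else:
            WhT = concat([self.W_h[g] for g in GATES], axis=0)
        st = _StackedCell(
            H=self.hidden_dim,
            WxT=_T(concat([self.W_x[g] for g in GATES], axis=0)),
            WhT=_T(WhT),
            b=concat([self.b[g] for g in GATES], axis=0),
        )
        if self.W_skip is not None:
            st.WskipT = _T(concat([self.W_skip[g] for g in GATES], axis=0))
        if self.W_lag is not None:
            st.WlagT = [
                _T(concat([self.W_lag[g][l] for g in GATES], axis=0))
                for l in range(len(self.W_lag["f"]))
            ]
        return st


def _T(t: Tensor) -> Tensor:
    from .autodiff import transpose

    return transpose(t)


@dataclass
class _StackedCell:
    H: int
    WxT: Tensor  # (input, 4H)
    WhT: Tensor  # (hidden, 4H)
    b: Tensor  # (4H,)
    WskipT: Optional[Tensor] = None
    WlagT: Optional[list] = None


@dataclass
class CellState:
    """Hidden and cell state, same length (the hidden dimension)."""

    h: Tensor
    c: Tensor

    def __post_init__(self):
        self.h = as_tensor(self.h)
        self.c = as_tensor(self.c)
        if self.h.shape != self.c.shape:
            raise ValueError(f"h shape {self.h.shape} != c shape {self.c.shape}")
        if not (np.all(np.isfinite(self.h.value)) and np.all(np.isfinite(self.c.value))):
            raise ValueError("non-finite cell state")

    @classmethod
    def zeros(cls, hidden_dim: int, batch: Optional[int] = None) -> "CellState":
        shape = (hidden_dim,) if batch is None else (batch, hidden_dim)
        return cls(Tensor(np.zeros(shape)), Tensor(np.zeros(shape)))


class HistoryBuffer:
    """The last ``skip`` hidden states h_{t-1}, ..., h_{t-skip}.

    ``get(lag)`` returns h_{t-lag}; entries referring to time indices <= 0
    are zero vectors by convention. ``t`` is the 1-based index of the step
    about to be computed.
    """

    def __init__(self, skip: int, hidden_dim: int, batch: Optional[int] = None, t: int = 1):
        if skip < 1:
            raise ValueError("skip must be >= 1")
        shape = (hidden_dim,) if batch is None else (batch, hidden_dim)
        self._zero_shape = shape
        self._entries: list[Tensor] = [Tensor(np.zeros(shape)) for _ in range(skip)]
        self.skip = skip
        self.t = t

    @classmethod
    def from_states(cls, states: Sequence, skip: int, hidden_dim: int, t: int,
                    batch: Optional[int] = None) -> "HistoryBuffer":
        """Build a buffer at time t from the full state history h_1..h_{t-1}."""
        buf = cls(skip, hidden_dim, batch=batch, t=1)
        for h in states:
            buf.push(as_tensor(h))
        if buf.t != t:
            raise ValueError(f"history of length {len(states)} inconsistent with t={t}")
        return buf

    def get(self, lag: int) -> Tensor:
        if not 1 <= lag <= self.skip:
            raise ValueError(f"lag must be in 1..{self.skip}, got {lag}")
        return self._entries[lag - 1]

    def push(self, h: Tensor) -> None:
        self._entries = [as_tensor(h)] + self._entries[:-1]
        self.t += 1


# -----------------------------------------------------------------------------
# core step
# -----------------------------------------------------------------------------
def _gate_split(pre: Tensor, H: int):
    """Split stacked pre-activations into f, i, o (sigmoid) and g (tanh)."""
    if pre.ndim == 1:
        sig = sigmoid(pre[: 3 * H])
        return sig[:H], sig[H : 2 * H], sig[2 * H : 3 * H], tanh(pre[3 * H :])
    sig = sigmoid(pre[:, : 3 * H])
    return (
        sig[:, :H],
        sig[:, H : 2 * H],
        sig[:, 2 * H : 3 * H],
        tanh(pre[:, 3 * H :]),
    )


def _core(pre_x: Tensor, h_prev: Tensor, c_prev: Tensor, st: _StackedCell,
          recur: Optional[Tensor] = None, extra: Optional[Tensor] = None):
    """One LSTM update from precomputed input projection ``pre_x``.

    ``recur`` overrides the standard W_h @ h_{t-1} term (variant E);
    ``extra`` is added to all gate pre-activations (variants B/D).
    """
    pre = pre_x + (recur if recur is not None else h_prev @ st.WhT)
    if extra is not None:
        pre = pre + extra
    f, i, o, g = _gate_split(pre, st.H)
    c = f * c_prev + i * g
    h = o * tanh(c)
    return h, c


def _pre_x(x: Tensor, st: _StackedCell) -> Tensor:
    return x @ st.WxT + st.b


def _check_x(x, p: CellParams) -> Tensor:
    x = as_tensor(x)
    if x.shape[-1] != p.input_dim:
        raise ValueError(f"input dim {x.shape[-1]} != expected {p.input_dim}")
    if not np.all(np.isfinite(x.value)):
        raise ValueError("non-finite input")
    return x


def lstm_step(x, prev: CellState, p: CellParams) -> CellState:
    """Standard LSTM update: gates f/i/o via sigmoid, candidate via tanh,
    c_t = f*c_{t-1} + i*g, h_t = o*tanh(c_t)."""
    x = _check_x(x, p)
    st = p.stack(SkipSpec("none"))
    h, c = _core(_pre_x(x, st), prev.h, prev.c, st)
    return CellState(h, c)


def _hist_check(hist: HistoryBuffer, t: int, skip: int) -> None:
    if hist.t != t:
        raise ValueError(f"history buffer at t={hist.t} inconsistent with step t={t}")
    if hist.skip < skip:
        raise ValueError(f"history depth {hist.skip} < skip {skip}")


def step_model_a(x, hist: HistoryBuffer, prev: CellState, p: CellParams, t: int,
                 skip: Optional[int] = None) -> CellState:
    """Discontinuous direct addition: h_t = N + h_{t-skip} at triggers."""
    skip = hist.skip if skip is None else skip
    _hist_check(hist, t, skip)
    x = _check_x(x, p)
    st = p.stack(SkipSpec("A", skip))
    h, c = _core(_pre_x(x, st), prev.h, prev.c, st)
    if is_trigger(t, skip):
        h = h + hist.get(skip)
    return CellState(h, c)


def step_model_b(x, hist: HistoryBuffer, prev: CellState, p: CellParams, t: int,
                 skip: Optional[int] = None) -> CellState:
    """Discontinuous weighted injection: at triggers every gate
    pre-activation gains W_skip @ h_{t-skip} on top of the usual terms."""
    skip = hist.skip if skip is None else skip
    _hist_check(hist, t, skip)
    x = _check_x(x, p)
    st = p.stack(SkipSpec("B", skip))
    extra = hist.get(skip) @ st.WskipT if is_trigger(t, skip) else None
    h, c = _core(_pre_x(x, st), prev.h, prev.c, st, extra=extra)
    return CellState(h, c)


def step_model_c(x, hist: HistoryBuffer, prev: CellState, p: CellParams, t: int,
                 skip: Optional[int] = None) -> CellState:
    """Continuous direct addition: h_t = N + h_{t-skip} at every step."""
    skip = hist.skip if skip is None else skip
    _hist_check(hist, t, skip)
    x = _check_x(x, p)
    st = p.stack(SkipSpec("C", skip))
    h, c = _core(_pre_x(x, st), prev.h, prev.c, st)
    h = h + hist.get(skip)
    return CellState(h, c)


def step_model_d(x, hist: HistoryBuffer, prev: CellState, p: CellParams, t: int,
                 skip: Optional[int] = None) -> CellState:
    """Continuous weighted injection: gate pre-activations gain
    W_skip @ h_{t-skip} at every step."""
    skip = hist.skip if skip is None else skip
    _hist_check(hist, t, skip)
    x = _check_x(x, p)
    st = p.stack(SkipSpec("D", skip))
    extra = hist.get(skip) @ st.WskipT
    h, c = _core(_pre_x(x, st), prev.h, prev.c, st, extra=extra)
    return CellState(h, c)


def step_model_e(x, hist: HistoryBuffer, prev: CellState, p: CellParams, t: int,
                 skip: Optional[int] = None) -> CellState:
    """Discontinuous multi-lag weighted injection: at triggers the recurrent
    term is the sum over lags l = 1..skip of W_l @ h_{t-l}; otherwise a
    standard step with the lag-1 matrix as the recurrent weight."""
    skip = hist.skip if skip is None else skip
    _hist_check(hist, t, skip)
    x = _check_x(x, p)
    st = p.stack(SkipSpec("E", skip))
    recur = None
    if is_trigger(t, skip):
        recur = hist.get(1) @ st.WlagT[0]
        for lag in range(2, skip + 1):
            recur = recur + hist.get(lag) @ st.WlagT[lag - 1]
    h, c = _core(_pre_x(x, st), prev.h, prev.c, st, recur=recur)
    return CellState(h, c)


def step_model_f(x, hist: HistoryBuffer, prev: CellState, p: CellParams, t: int,
                 skip: Optional[int] = None) -> CellState:
    """Discontinuous multi-lag direct addition: at triggers
    h_t = N + sum over s = 2..skip of h_{t-s}."""
    skip = hist.skip if skip is None else skip
    _hist_check(hist, t, skip)
    x = _check_x(x, p)
    st = p.stack(SkipSpec("F", skip))
    h, c = _core(_pre_x(x, st), prev.h, prev.c, st)
    if is_trigger(t, skip):
        for s in range(2, skip + 1):
            h = h + hist.get(s)
    return CellState(h, c)


_STEPS = {
    "A": step_model_a,
    "B": step_model_b,
    "C": step_model_c,
    "D": step_model_d,
    "E": step_model_e,
    "F": step_model_f,
}


# -----------------------------------------------------------------------------
# baseline cells
# -----------------------------------------------------------------------------
@dataclass
class RNNParams:
    """Elman cell: h_t = tanh(W_h h_{t-1} + W_x x_t + b)."""

    input_dim: int
    hidden_dim: int
    W_h: Tensor = None
    W_x: Tensor = None
    b: Tensor = None

    @classmethod
    def init(cls, input_dim, hidden_dim, rng=0):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        s = 1.0 / np.sqrt(hidden_dim)
        return cls(
            input_dim, hidden_dim,
            W_h=_uniform(rng, (hidden_dim, hidden_dim), s),
            W_x=_uniform(rng, (hidden_dim, input_dim), s),
            b=_uniform(rng, (hidden_dim,), s),
        )

    def parameters(self):
        return [self.W_h, self.W_x, self.b]


def rnn_step(x, prev_h, p: RNNParams) -> Tensor:
    x, prev_h = as_tensor(x), as_tensor(prev_h)
    return tanh(x @ _T(p.W_x) + prev_h @ _T(p.W_h) + p.b)


@dataclass
class GRUParams:
    """GRU cell with update gate z, reset gate r and candidate n."""

    input_dim: int
    hidden_dim: int
    W: dict = field(default_factory=dict)  # keys: zh, zx, rh, rx, nh, nx
    b: dict = field(default_factory=dict)  # keys: z, r, n

    @classmethod
    def init(cls, input_dim, hidden_dim, rng=0):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        s = 1.0 / np.sqrt(hidden_dim)
        p = cls(input_dim, hidden_dim)
        for k in ("z", "r", "n"):
            p.W[k + "h"] = _uniform(rng, (hidden_dim, hidden_dim), s)
            p.W[k + "x"] = _uniform(rng, (hidden_dim, input_dim), s)
            p.b[k] = _uniform(rng, (hidden_dim,), s)
        return p

    def parameters(self):
        return list(self.W.values()) + list(self.b.values())


def gru_step(x, prev_h, p: GRUParams) -> Tensor:
    """h_t = z*h_{t-1} + (1-z)*n with n = tanh(W_nx x + r*(W_nh h) + b_n);
    a saturated update gate (z -> 1) carries the previous state through."""
    x, prev_h = as_tensor(x), as_tensor(prev_h)
    z = sigmoid(x @ _T(p.W["zx"]) + prev_h @ _T(p.W["zh"]) + p.b["z"])
    r = sigmoid(x @ _T(p.W["rx"]) + prev_h @ _T(p.W["rh"]) + p.b["r"])
    n = tanh(x @ _T(p.W["nx"]) + r * (prev_h @ _T(p.W["nh"])) + p.b["n"])
    return z * prev_h + (1.0 - z) * n


# -----------------------------------------------------------------------------
# unrolling
# -----------------------------------------------------------------------------
def unroll(sequence, spec: SkipSpec, p: CellParams,
           init: Optional[CellState] = None) -> list[CellState]:
    """Apply the variant step over t = 1..T, maintaining the history buffer.

    ``sequence`` is (T, input_dim) for a single sequence or
    (batch, T, input_dim) for a batch; returned states match the layout.
    With ``spec.variant == 'none'`` this is a plain LSTM unroll.
    """
    xs = as_tensor(sequence)
    if xs.ndim == 2:
        states = _unroll_batched(xs.reshape(1, *xs.shape), spec, p,
                                 init=_promote_state(init))
        return [CellState(s.h[0], s.c[0]) for s in states]
    if xs.ndim != 3:
        raise ValueError("sequence must be (T, D) or (B, T, D)")
    return _unroll_batched(xs, spec, p, init=init)


def _promote_state(init: Optional[CellState]) -> Optional[CellState]:
    if init is None:
        return None
    return CellState(init.h.reshape(1, -1), init.c.reshape(1, -1))


def _unroll_batched(xs: Tensor, spec: SkipSpec, p: CellParams,
                    init: Optional[CellState] = None,
                    return_h_only: bool = False):
    B, T, D = xs.shape
    if T == 0:
        raise ValueError("empty sequence")
    if D != p.input_dim:
        raise ValueError(f"input dim {D} != expected {p.input_dim}")
    st = p.stack(spec)
    H = st.H
    skip = spec.skip if spec.variant != "none" else 1
    # project all inputs in one matmul; biases folded in
    xproj = (xs.reshape(B * T, D) @ st.WxT + st.b).reshape(B, T, 4 * H)
    if init is None:
        init = CellState.zeros(H, batch=B)
    h, c = init.h, init.c
    past = [Tensor(np.zeros((B, H))) for _ in range(skip)]  # h_{t-1}..h_{t-skip}
    variant = spec.variant
    out = []
    hs = []
    for t in range(1, T + 1):
        pre_x = xproj[:, t - 1]
        recur = None
        extra = None
        if variant == "B":
            if is_trigger(t, skip):
                extra = past[skip - 1] @ st.WskipT
        elif variant == "D":
            extra = past[skip - 1] @ st.WskipT
        elif variant == "E":
            if is_trigger(t, skip):
                recur = past[0] @ st.WlagT[0]
                for lag in range(2, skip + 1):
                    recur = recur + past[lag - 1] @ st.WlagT[lag - 1]
        h_new, c_new = _core(pre_x, h, c, st, recur=recur, extra=extra)
        if variant == "A":
            if is_trigger(t, skip):
                h_new = h_new + past[skip - 1]
        elif variant == "C":
            h_new = h_new + past[skip - 1]
        elif variant == "F":
            if is_trigger(t, skip):
                for s in range(2, skip + 1):
                    h_new = h_new + past[s - 1]
        past = [h_new] + past[:-1]
        h, c = h_new, c_new
        if return_h_only:
            hs.append(h)
        else:
            out.append(CellState(h, c))
    return hs if return_h_only else out
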
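"""The classifier network: dense feature extractor + three recurrent layers.

Tabular records (e.g. a 16-feature diabetes questionnaire) first pass
through a tanh dense stack of widths 128/64/32/16; the 128-unit first
layer's activations are reshaped row-major to a 32x4 pseudo-sequence that
the recurrent layers can consume. (The stack's later layers are part of the
published architecture and are computed, but only the 128-wide activation
map has a width divisible into 32 timesteps x 4 features, so it feeds the
reshape.) Genuine sequence data bypasses the extractor.

The recurrent classifier is three skip-augmented LSTM layers (hidden sizes
18, 8, 5 by default) run in series — layer l's hidden sequence is layer
l+1's input — followed by a dense softmax readout from the final
timestep's hidden state of the last layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, as_tensor, no_grad, softmax, tanh, transpose
from .cells import CellParams, SkipSpec, _unroll_batched

__all__ = [
    "ExtractorParams",
    "NetworkConfig",
    "SSNetwork",
    "feature_extract",
    "predict",
]

PSEUDO_SEQ_SHAPE = (32, 4)


@dataclass
class ExtractorParams:
    """Dense tanh stack turning a feature vector into a pseudo-sequence."""

    input_dim: int
    widths: tuple = (128, 64, 32, 16)
    layers: list = field(default_factory=list)  # [(W, b), ...], W is (out, in)

    @classmethod
    def init(cls, input_dim: int, widths=(128, 64, 32, 16), rng=0) -> "ExtractorParams":
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        if widths[0] != PSEUDO_SEQ_SHAPE[0] * PSEUDO_SEQ_SHAPE[1]:
            raise ValueError(
                f"first extractor width must be {PSEUDO_SEQ_SHAPE[0] * PSEUDO_SEQ_SHAPE[1]} "
                f"to reshape into {PSEUDO_SEQ_SHAPE}, got {widths[0]}"
            )
        p = cls(input_dim=input_dim, widths=tuple(widths))
        fan_in = input_dim
        for w in widths:
            s = 1.0 / np.sqrt(fan_in)
            W = Tensor(rng.uniform(-s, s, size=(w, fan_in)), requires_grad=True)
            b = Tensor(rng.uniform(-s, s, size=(w,)), requires_grad=True)
            p.layers.append((W, b))
            fan_in = w
        return p

    def named_parameters(self, prefix: str = "extractor.") -> dict[str, Tensor]:
        out = {}
        for i, (W, b) in enumerate(self.layers):
            out[f"{prefix}dense{i}.W"] = W
            out[f"{prefix}dense{i}.b"] = b
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())


def feature_extract(record, p: ExtractorParams) -> Tensor:
    """Map feature vectors to 32x4 pseudo-sequences.

    ``record`` is (features,) or (batch, features); the result is
    (32, 4) or (batch, 32, 4), the row-major reshape of the first dense
    layer's tanh activations. The remaining layers of the stack are
    evaluated as part of the forward pass but do not feed the reshape.
    """
    x = as_tensor(record)
    single = x.ndim == 1
    if single:
        x = x.reshape(1, -1)
    if x.shape[1] != p.input_dim:
        raise ValueError(f"record has {x.shape[1]} features, expected {p.input_dim}")
    a = x
    first = None
    for W, b in p.layers:
        a = tanh(a @ transpose(W) + b)
        if first is None:
            first = a
    B = first.shape[0]
    seq = first.reshape(B, *PSEUDO_SEQ_SHAPE)
    return seq[0] if single else seq


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture description for :class:`SSNetwork`.

    ``skip_specs`` may be a single :class:`SkipSpec` (applied to every
    recurrent layer) or one spec per layer.
    """

    n_classes: int
    input_mode: str = "sequence"  # 'sequence' | 'tabular'
    input_dim: int = 1  # per-timestep features (sequence) or feature count (tabular)
    hidden_dims: tuple = (18, 8, 5)
    skip_specs: object = SkipSpec("none")
    extractor_widths: tuple = (128, 64, 32, 16)

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.input_mode not in ("sequence", "tabular"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")

    def layer_specs(self) -> list[SkipSpec]:
        if isinstance(self.skip_specs, SkipSpec):
            return [self.skip_specs] * len(self.hidden_dims)
        specs = list(self.skip_specs)
        if len(specs) != len(self.hidden_dims):
            raise ValueError("need one SkipSpec per recurrent layer")
        return specs


class SSNetwork:
    """Feature extractor (tabular mode) + stacked skip-LSTM + softmax head."""

    def __init__(self, config: NetworkConfig, rng=0):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.config = config
        specs = config.layer_specs()
        self.extractor: Optional[ExtractorParams] = None
        if config.input_mode == "tabular":
            self.extractor = ExtractorParams.init(
                config.input_dim, config.extractor_widths, rng=rng
            )
            in_dim = 4  # pseudo-sequence feature width
        else:
            in_dim = config.input_dim
        self.cells: list[CellParams] = []
        for H, spec in zip(config.hidden_dims, specs):
            self.cells.append(CellParams.init(in_dim, H, spec=spec, rng=rng))
            in_dim = H
        s = 1.0 / np.sqrt(in_dim)
        self.W_out = Tensor(rng.uniform(-s, s, size=(config.n_classes, in_dim)),
                            requires_grad=True)
        self.b_out = Tensor(rng.uniform(-s, s, size=(config.n_classes,)),
                            requires_grad=True)

    # -- parameters ----------------------------------------------------------
    def named_parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        if self.extractor is not None:
            out.update(self.extractor.named_parameters())
        for i, cell in enumerate(self.cells):
            out.update(cell.named_parameters(prefix=f"layer{i}."))
        out["readout.W"] = self.W_out
        out["readout.b"] = self.b_out
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    # -- forward -------------------------------------------------------------
    def forward(self, X) -> Tensor:
        """Class probabilities (batch, K) for a batch of inputs.

        Sequence mode expects (batch, T, input_dim); tabular mode expects
        (batch, features) and routes through the extractor first.
        """
        x = as_tensor(X)
        if self.config.input_mode == "tabular":
            if x.ndim != 2:
                raise ValueError("tabular mode expects (batch, features)")
            seq = feature_extract(x, self.extractor)
        else:
            if x.ndim != 3:
                raise ValueError("sequence mode expects (batch, T, input_dim)")
            if x.shape[1] == 0:
                raise ValueError("empty sequence")
            seq = x
        specs = self.config.layer_specs()
        hs = None
        for cell, spec in zip(self.cells, specs):
            hs = _unroll_batched(seq, spec, cell, return_h_only=True)
            # next layer consumes this layer's hidden sequence
            seq = _stack_time(hs)
        logits = hs[-1] @ transpose(self.W_out) + self.b_out
        return softmax(logits, axis=-1)

    def predict_proba(self, X) -> np.ndarray:
        with no_grad():
            return self.forward(X).value

    def predict(self, X) -> np.ndarray:
        return predict(self.predict_proba(X))


def _stack_time(hs: Sequence[Tensor]) -> Tensor:
    """(B, H) per timestep -> (B, T, H), differentiable."""
    from .autodiff import concat

    return concat([h.reshape(h.shape[0], 1, h.shape[1]) for h in hs], axis=1)


def predict(probabilities) -> np.ndarray:
    """Argmax class index; ties break toward the lowest index."""
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability vector")
    if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("probabilities do not sum to 1")
    return np.argmax(p, axis=-1)
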
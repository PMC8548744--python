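"""scikit-learn style estimator wrapping the skip-LSTM network.

`SkipLSTMClassifier` composes with sklearn pipelines and model selection:
it exposes ``get_params``/``set_params``, validates inputs in ``fit`` and
stores fitted state in trailing-underscore attributes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from .cells import SkipSpec
from .network import NetworkConfig, SSNetwork, predict as _argmax
from .training import TrainConfig, train

__all__ = ["SkipLSTMClassifier"]


class SkipLSTMClassifier(BaseEstimator, ClassifierMixin):
    """Sequence / tabular classifier built on skip-augmented LSTM layers.

    Parameters
    ----------
    variant : {'none', 'A', 'B', 'C', 'D', 'E', 'F'}
        How the hidden state from `skip` steps back is injected; 'none'
        is the plain LSTM baseline.
    skip : int
        The skip order (lag of the auxiliary connection), >= 2.
    hidden_dims : tuple of int
        Hidden sizes of the stacked recurrent layers.
    extractor_widths : tuple of int
        Dense feature-extractor widths used in tabular mode; the first
        width is reshaped to the 32x4 pseudo-sequence.
    input_mode : {'auto', 'sequence', 'tabular'}
        'auto' infers from X's dimensionality in ``fit`` (3-D arrays are
        sequences, 2-D arrays tabular records).
    learning_rate, epochs, batch_size, shuffle
        Plain-SGD training recipe (defaults 0.01 / 50 / 32 / True).
    random_state : int
        Seeds initialisation and batch shuffling.

    Attributes
    ----------
    classes_ : ndarray
        Sorted unique labels seen in ``fit``.
    net_ : SSNetwork
        The trained network.
    loss_curve_ : list of float
        Mean training loss per epoch.
    """

    def __init__(
        self,
        variant: str = "none",
        skip: int = 3,
        hidden_dims: tuple = (18, 8, 5),
        extractor_widths: tuple = (128, 64, 32, 16),
        input_mode: str = "auto",
        learning_rate: float = 0.01,
        epochs: int = 50,
        batch_size: int = 32,
        shuffle: bool = True,
        random_state: int = 0,
    ):
        self.variant = variant
        self.skip = skip
        self.hidden_dims = hidden_dims
        self.extractor_widths = extractor_widths
        self.input_mode = input_mode
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.shuffle = shuffle
        self.random_state = random_state

    # -- internals -----------------------------------------------------------
    def _resolve_mode(self, X: np.ndarray) -> str:
        if self.input_mode != "auto":
            return self.input_mode
        return "sequence" if X.ndim == 3 else "tabular"

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim not in (2, 3):
            raise ValueError("X must be (n, features) or (n, T, features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y):
        X = self._validate_X(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        mode = self._resolve_mode(X)
        input_dim = X.shape[-1] if mode == "sequence" else X.shape[1]
        spec = SkipSpec(self.variant, self.skip) if self.variant != "none" else SkipSpec("none")
        config = NetworkConfig(
            n_classes=len(self.classes_),
            input_mode=mode,
            input_dim=input_dim,
            hidden_dims=tuple(self.hidden_dims),
            skip_specs=spec,
            extractor_widths=tuple(self.extractor_widths),
        )
        self.net_ = SSNetwork(config, rng=self.random_state)
        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.random_state,
            shuffle=self.shuffle,
        )
        self.loss_curve_ = train(self.net_, X, y_idx, cfg)
        self.n_features_in_ = input_dim
        self.input_mode_ = mode
        return self

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise NotFittedError("fit must be called before prediction")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._validate_X(X)
        out = []
        # bounded-memory batched inference
        for start in range(0, len(X), 256):
            out.append(self.net_.predict_proba(X[start : start + 256]))
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        return self.classes_[_argmax(self.predict_proba(X))]
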
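"""Scikit-learn style estimators wrapping the window classifiers.

``ConvNeXt1DClassifier`` and ``BaselineCNNClassifier`` expose the networks
through the familiar fit / predict_proba / predict surface so they compose
with sklearn pipelines and model selection. ``X`` is ``(n_windows, 1250)``
or ``(n_windows, 1, 1250)`` float arrays of 10 s single-lead windows at
125 Hz; ``y`` is binary (1 = AFib/AFL).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .augment import AugmentConfig
from .io import WindowSet
from .nn.models import BaselineConfig, ModelConfig, build_baseline, build_model
from .train import TrainConfig, train

__all__ = ["ConvNeXt1DClassifier", "BaselineCNNClassifier"]


class _WindowClassifier(ClassifierMixin, BaseEstimator):
    """Shared fit/predict machinery; subclasses choose the architecture."""

    def __init__(self, epochs=10, batch_size=32, learning_rate=3e-4,
                 weight_decay=0.05, augment=True, validation_fraction=0.0,
                 seed=0, verbose=False):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.augment = augment
        self.validation_fraction = validation_fraction
        self.seed = seed
        self.verbose = verbose

    def _build(self):  # pragma: no cover - abstract
        raise NotImplementedError

    @staticmethod
    def _as_windows(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[:, None, :]
        if X.ndim != 3:
            raise ValueError("X must be (n, L) or (n, C, L)")
        return X

    def fit(self, X, y):
        X = self._as_windows(X)
        y = np.asarray(y).astype(np.int8)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need both classes to fit")
        fs = X.shape[2] / 10.0  # windows are 10 s by construction
        ws = WindowSet(data=X, labels=y, fs=fs, window_len_s=10.0)

        rng = np.random.default_rng(self.seed)
        n_val = int(round(self.validation_fraction * len(ws)))
        val_ws = None
        train_ws = ws
        if n_val >= 2:
            order = rng.permutation(len(ws))
            val_idx, tr_idx = order[:n_val], order[n_val:]
            if len(np.unique(y[val_idx])) == 2 and len(np.unique(y[tr_idx])) == 2:
                val_ws, train_ws = ws.subset(val_idx), ws.subset(tr_idx)

        aug = AugmentConfig() if self.augment else AugmentConfig.disabled()
        cfg = TrainConfig(batch_size=self.batch_size, epochs=self.epochs,
                          learning_rate=self.learning_rate,
                          weight_decay=self.weight_decay, seed=self.seed,
                          augment=aug)
        self.model_ = self._build()
        self.model_, self.history_ = train(self.model_, train_ws, val_ws, cfg,
                                           verbose=self.verbose)
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = self._as_windows(X)
        return self.model_.predict_proba(X)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]

    def decision_function(self, X):
        p = self.predict_proba(X)
        return p[:, 1] - p[:, 0]


class ConvNeXt1DClassifier(_WindowClassifier):
    """1D ConvNeXtV2 AFib/AFL window classifier (~770 k parameters)."""

    def __init__(self, epochs=10, batch_size=32, learning_rate=3e-4,
                 weight_decay=0.05, augment=True, validation_fraction=0.0,
                 seed=0, verbose=False, dims=(16, 32, 64, 128),
                 depths=(3, 3, 9, 3)):
        super().__init__(epochs, batch_size, learning_rate, weight_decay,
                         augment, validation_fraction, seed, verbose)
        self.dims = dims
        self.depths = depths

    def _build(self):
        return build_model(ModelConfig(dims=tuple(self.dims),
                                       depths=tuple(self.depths),
                                       seed=self.seed))


class BaselineCNNClassifier(_WindowClassifier):
    """Four-block strided-CNN baseline (~70 k parameters)."""

    def __init__(self, epochs=10, batch_size=32, learning_rate=3e-4,
                 weight_decay=0.05, augment=True, validation_fraction=0.0,
                 seed=0, verbose=False, channels=(16, 32, 64, 128),
                 dropout=0.25):
        super().__init__(epochs, batch_size, learning_rate, weight_decay,
                         augment, validation_fraction, seed, verbose)
        self.channels = channels
        self.dropout = dropout

    def _build(self):
        return build_baseline(BaselineConfig(channels=tuple(self.channels),
                                             dropout=self.dropout,
                                             seed=self.seed))
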
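"""scikit-learn-style estimators wrapping the pipeline stages.

``SpectrogramImager`` (transformer) and ``CapsNetClassifier`` /
``ShallowNetClassifier`` compose in an sklearn ``Pipeline``: the imager
emits flattened 588-pixel rows by default, which the capsule classifier
accepts alongside (n, 3, 14, 14) stacks.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .capsnet import CapsNetConfig, CapsNetModel
from .imaging import DEFAULT_BAND_BINS, IMAGE_SHAPE, StftConfig, epochs_to_images
from .shallownet import ShallowNetConfig, ShallowNetModel
from .training import TrainConfig, fit_sgd

__all__ = ["SpectrogramImager", "CapsNetClassifier", "ShallowNetClassifier"]


class SpectrogramImager(TransformerMixin, BaseEstimator):
    """Stateless transform: epochs (n, 3, 500) -> normalized MI images.

    With ``flatten=True`` (default) the output is (n, 588) so the
    transformer chains with 2D-array consumers; otherwise (n, 3, 14, 14).
    """

    def __init__(self, sampling_rate: float = 250.0, window_len: int = 128,
                 overlap: int = 100, band_bins: tuple[int, int] = DEFAULT_BAND_BINS,
                 flatten: bool = True):
        self.sampling_rate = sampling_rate
        self.window_len = window_len
        self.overlap = overlap
        self.band_bins = band_bins
        self.flatten = flatten

    def fit(self, X, y=None):
        self.n_features_in_ = np.prod(np.asarray(X).shape[1:])
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 2:  # flattened epochs
            X = X.reshape(len(X), 3, -1)
        cfg = StftConfig(window_len=self.window_len, overlap=self.overlap)
        images = epochs_to_images(X, self.sampling_rate, cfg, tuple(self.band_bins))
        return images.reshape(len(images), -1) if self.flatten else images


class _SGDNetClassifier(ClassifierMixin, BaseEstimator):
    """Shared fit/predict plumbing for the two network classifiers."""

    _input_shape: tuple[int, ...]  # set by subclasses

    def _reshape(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2 and X.shape[1] == int(np.prod(self._input_shape)):
            X = X.reshape((len(X),) + self._input_shape)
        if X.shape[1:] != self._input_shape:
            raise ValueError(
                f"X must have shape (n,)+{self._input_shape} or "
                f"(n, {int(np.prod(self._input_shape))}), got {X.shape}"
            )
        return X

    def _train_cfg(self) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size, epochs=self.epochs,
            learning_rate=self.learning_rate, momentum=self.momentum,
            seed=self.random_state, early_stopping=self.early_stopping,
            patience=self.patience, validation_fraction=self.validation_fraction,
        )

    def fit(self, X, y):
        X = self._reshape(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError(f"exactly 2 classes required, got {len(self.classes_)}")
        self.model_ = self._build_model()
        self.history_ = fit_sgd(self.model_, X, y_idx, self._train_cfg())
        self.n_features_in_ = int(np.prod(self._input_shape))
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.classes_[self.model_.predict(self._reshape(X))]

    def score_curve(self):
        check_is_fitted(self, "history_")
        return self.history_.to_frame()


class CapsNetClassifier(_SGDNetClassifier):
    """Capsule-network classifier for 3 x 14 x 14 time-frequency images.

    Parameters mirror the network architecture (convolution channels,
    primary-capsule channels/dimension, class-capsule dimension, routing
    iterations, reconstruction regularizer) and the SGD schedule.
    ``decision_function`` exposes the class-capsule norms.
    """

    _input_shape = IMAGE_SHAPE

    def __init__(self, conv_channels: int = 4, primary_channels: int = 128,
                 primary_dim: int = 4, mi_dim: int = 8, routing_iters: int = 1,
                 reconstruction: bool = True, batch_size: int = 50,
                 epochs: int = 500, learning_rate: float = 0.01,
                 momentum: float = 0.7, early_stopping: bool = False,
                 patience: int = 10, validation_fraction: float = 0.2,
                 random_state: int = 0):
        self.conv_channels = conv_channels
        self.primary_channels = primary_channels
        self.primary_dim = primary_dim
        self.mi_dim = mi_dim
        self.routing_iters = routing_iters
        self.reconstruction = reconstruction
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.early_stopping = early_stopping
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _build_model(self) -> CapsNetModel:
        cfg = CapsNetConfig(
            conv_channels=self.conv_channels,
            primary_channels=self.primary_channels,
            primary_dim=self.primary_dim, mi_dim=self.mi_dim,
            routing_iters=self.routing_iters, reconstruction=self.reconstruction,
        )
        return CapsNetModel(cfg, seed=self.random_state)

    def decision_function(self, X) -> np.ndarray:
        """Class-capsule norms (n, 2): the capsule analogue of confidence."""
        check_is_fitted(self, "model_")
        norms, *_ = self.model_.forward(self._reshape(X))
        return norms


class ShallowNetClassifier(_SGDNetClassifier):
    """ShallowNet baseline on raw 3 x 500 band-passed epochs."""

    _input_shape = (3, 500)

    def __init__(self, dropout_rate: float = 0.5, batch_size: int = 50,
                 epochs: int = 500, learning_rate: float = 0.01,
                 momentum: float = 0.7, early_stopping: bool = False,
                 patience: int = 10, validation_fraction: float = 0.2,
                 random_state: int = 0):
        self.dropout_rate = dropout_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.early_stopping = early_stopping
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _build_model(self) -> ShallowNetModel:
        cfg = ShallowNetConfig(dropout_rate=self.dropout_rate)
        return ShallowNetModel(cfg, seed=self.random_state)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.forward(self._reshape(X))
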
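"""Scikit-learn estimator interface to the profusion-level classifier.

:class:`ProfusionClassifier` wraps model construction, the balanced-batch
training loop and batched inference behind the standard fit/predict
surface, so the classifier composes with sklearn model selection and
pipelines.  Input ``X`` is an array of grayscale tiles, either
``(n, size, size)`` or flattened ``(n, size*size)``, with pixel values in
[0, 1].

Defaults are the desk-scale configuration (small backbone, 64-pixel tiles,
30 epochs); the full-scale recipe (resnet18 backbone, 256-pixel tiles,
lr 1e-4, 300 epochs) is a parameter choice away.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import network, objectives
from .config import LossConfig, ModelConfig, TrainConfig

__all__ = ["ProfusionClassifier"]


class ProfusionClassifier(TransformerMixin, ClassifierMixin, BaseEstimator):
    """Texture-encoding ordinal classifier for lung-subregion profusion levels.

    Parameters mirror the model/training/loss configuration; fitted
    attributes follow sklearn conventions (``model_``, ``history_``,
    ``classes_``, ``class_prior_``).  ``transform`` returns the
    L2-normalized texture encodings, making the estimator usable as a
    feature extractor inside a pipeline.
    """

    def __init__(self, input_size: int = 64, backbone: str = "small",
                 reduced_channels: int = 128, codewords: int = 8,
                 suppression: float = 0.2, n_levels: int = 4,
                 alpha: float = 0.5, beta: float = 0.5, tau: float = 0.1,
                 supcon_variant: str = "in", learning_rate: float = 1e-3,
                 batch_size: int = 16, epochs: int = 30,
                 augment_flip: bool = True, augment_rotation: float = 10.0,
                 random_state: int = 0):
        self.input_size = input_size
        self.backbone = backbone
        self.reduced_channels = reduced_channels
        self.codewords = codewords
        self.suppression = suppression
        self.n_levels = n_levels
        self.alpha = alpha
        self.beta = beta
        self.tau = tau
        self.supcon_variant = supcon_variant
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.augment_flip = augment_flip
        self.augment_rotation = augment_rotation
        self.random_state = random_state

    # -- config assembly ----------------------------------------------

    def _model_config(self) -> ModelConfig:
        return ModelConfig(input_size=self.input_size, backbone=self.backbone,
                           reduced_channels=self.reduced_channels,
                           codewords=self.codewords, suppression=self.suppression,
                           classes=self.n_levels, seed=self.random_state).validate()

    def _train_config(self) -> TrainConfig:
        return TrainConfig(learning_rate=self.learning_rate, batch_size=self.batch_size,
                           epochs=self.epochs, augment_flip=self.augment_flip,
                           augment_rotation=self.augment_rotation,
                           seed=self.random_state).validate()

    def _loss_config(self) -> LossConfig:
        return LossConfig(alpha=self.alpha, beta=self.beta, tau=self.tau,
                          supcon_variant=self.supcon_variant).validate()

    def _as_images(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        s = self.input_size
        if X.ndim == 2 and X.shape[1] == s * s:
            X = X.reshape(-1, s, s)
        if X.ndim != 3 or X.shape[1:] != (s, s):
            raise ValueError(f"X must be (n, {s}, {s}) or (n, {s * s}), got {X.shape}")
        return X

    # -- sklearn surface ----------------------------------------------

    def fit(self, X, y):
        X = self._as_images(X)
        y = np.asarray(y, dtype=np.intp)
        self.model_ = network.build_model(self._model_config())
        self.class_prior_ = objectives.class_frequencies(y, self.n_levels)
        self.history_ = network.train_arrays(
            self.model_, X, y, self._train_config(), self._loss_config(),
            class_prior=self.class_prior_)
        self.classes_ = np.arange(self.n_levels)
        return self

    def _batched_forward(self, X, chunk: int = 32):
        X = self._as_images(X)
        zs, ss = [], []
        for i in range(0, len(X), chunk):
            z, s = self.model_.forward(X[i : i + chunk], train=False)
            zs.append(z)
            ss.append(s)
        return np.concatenate(zs), np.concatenate(ss)

    def decision_function(self, X):
        """Raw per-level scores from the fully connected head."""
        check_is_fitted(self, "model_")
        return self._batched_forward(X)[1]

    def predict_proba(self, X):
        """Predicted label distribution (softmax of the scores)."""
        return objectives.predicted_distribution(self.decision_function(X))

    def predict(self, X):
        """Argmax profusion level, ties toward the lower level."""
        return network.predict_profusion(self.decision_function(X))

    def transform(self, X):
        """L2-normalized flattened texture encodings (the embedding space)."""
        check_is_fitted(self, "model_")
        return self._batched_forward(X)[0]

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = False
        return tags
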
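"""scikit-learn estimators wrapping the CNN architectures.

``AdjCNNClassifier`` consumes raw trials ``(n, channels, samples)``,
optionally applies the structural graph embedding, and trains the wide-
kernel CNN.  ``PLVCNNClassifier`` consumes precomputed PLV matrices
``(n, C, C)`` (compose with :class:`~migraph.connectivity.PLVTransform`
in a pipeline to start from raw trials).  ``BaselineCNNClassifier`` holds
the two graph-ablated baselines.  All follow the sklearn contract:
``get_params``/``set_params``, ``fit`` returning self, fitted attributes
with trailing underscores, ``predict``/``predict_proba``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .embedding import scale_trials, _embed_array
from .models import (
    build_ablation_baseline,
    build_adj_cnnm,
    build_plv_cnnm,
    default_train_config,
)
from .montage import build_adjacency, build_layout
from .nn import TrainConfig, instantiate

__all__ = ["AdjCNNClassifier", "PLVCNNClassifier", "BaselineCNNClassifier"]


class _CNNClassifierBase(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery; subclasses build the ModelSpec."""

    def _build_spec(self, input_shape, n_classes):  # pragma: no cover
        raise NotImplementedError

    def _prepare_X(self, X):
        return np.asarray(X)

    def _train_config(self) -> TrainConfig:
        cfg = default_train_config(self.model_spec_.name, seed=self.seed)
        if self.learning_rate is not None:
            cfg.learning_rate = self.learning_rate
        if self.batch_size is not None:
            cfg.batch_size = self.batch_size
        if self.max_epochs is not None:
            cfg.max_epochs = self.max_epochs
        if self.patience is not None:
            cfg.early_stop_patience = self.patience
        return cfg

    def fit(self, X, y):
        X = self._prepare_X(X)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError(f"expected 3-D input (n, height, width), got {X.shape}")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.model_spec_ = self._build_spec((X.shape[1], X.shape[2], 1), len(self.classes_))
        self.network_ = instantiate(self.model_spec_, seed=self.seed)
        cfg = self._train_config()
        self.network_.fit(X.astype(np.float32), y_idx, cfg)
        self.train_config_ = cfg
        self.history_ = self.network_.history
        return self

    def predict_proba(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "network_")
        return self.network_.predict_proba(self._prepare_X(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class AdjCNNClassifier(_CNNClassifierBase):
    """Wide-kernel CNN on (optionally) graph-embedded trials.

    Parameters
    ----------
    embed : apply the normalised-adjacency embedding before training
        (``False`` gives the "no structural graph" ablation).
    montage : packaged montage for the embedding.
    scale : per-trial z-scoring mode applied before the embedding
        ("trial", "channel" or None).
    filters, kernel_width : first-layer kernel bank (defaults 64, 45).
    learning_rate, batch_size, max_epochs, patience : overrides of the
        default regime (Adam 1e-4, batch 128, 1000 epochs, patience 250).
    """

    def __init__(self, *, embed=True, montage="bci2a-22", scale="trial",
                 filters=64, kernel_width=45, learning_rate=None, batch_size=None,
                 max_epochs=None, patience=None, validation_fraction=0.1, seed=0):
        self.embed = embed
        self.montage = montage
        self.scale = scale
        self.filters = filters
        self.kernel_width = kernel_width
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _build_spec(self, input_shape, n_classes):
        name = "adj-cnnm" if self.embed else "cnn-no-adj-graph"
        spec = build_adj_cnnm(input_shape, n_classes, filters=self.filters,
                              kernel_width=self.kernel_width)
        from .nn import ModelSpec

        return ModelSpec(name=name, input_shape=spec.input_shape,
                         layers=spec.layers, class_count=n_classes)

    def _prepare_X(self, X):
        X = np.asarray(X)
        if X.ndim != 3:
            return X
        if not hasattr(self, "graph_"):
            self.graph_ = build_adjacency(build_layout(self.montage))
        X = scale_trials(X, self.scale)
        if self.embed:
            if X.shape[1] != len(self.graph_.channels):
                raise ValueError(
                    f"{X.shape[1]} channels do not match montage "
                    f"{self.montage!r} ({len(self.graph_.channels)} channels)"
                )
            X = _embed_array(X, self.graph_.A_hat)
        return X.astype(np.float32)

    def _train_config(self):
        cfg = super()._train_config()
        cfg.validation_fraction = self.validation_fraction
        return cfg


class PLVCNNClassifier(_CNNClassifierBase):
    """Small 2-D CNN on per-trial PLV connectivity matrices.

    Expects ``X`` of shape (n, C, C); each slice must be a square
    connectivity matrix.  Defaults: filters (32, 64), 3x3 kernels, Adam
    1e-3, batch 64, 800 epochs, no early stopping.
    """

    def __init__(self, *, filters=(32, 64), kernel=(3, 3), learning_rate=None,
                 batch_size=None, max_epochs=None, patience=None, seed=0):
        self.filters = filters
        self.kernel = kernel
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    def _build_spec(self, input_shape, n_classes):
        return build_plv_cnnm(input_shape, n_classes, filters=tuple(self.filters),
                              kernel=tuple(self.kernel))


class BaselineCNNClassifier(_CNNClassifierBase):
    """Graph-ablated baseline CNNs applied directly to raw trials.

    ``which="no_adj_graph"`` reuses the wide-kernel architecture without
    the embedding; ``which="no_plv_graph"`` adapts the functional
    architecture to raw band-passed trials (first kernel 3x45).
    """

    def __init__(self, *, which="no_plv_graph", scale="trial", learning_rate=None,
                 batch_size=None, max_epochs=None, patience=None, seed=0):
        self.which = which
        self.scale = scale
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    def _build_spec(self, input_shape, n_classes):
        return build_ablation_baseline(self.which, input_shape, n_classes)

    def _prepare_X(self, X):
        X = np.asarray(X)
        if X.ndim == 3:
            X = scale_trials(X, self.scale)
        return X.astype(np.float32)
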
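"""Network assembly, Adam optimisation and the training loop.

``instantiate`` turns a :class:`~migraph.nn.spec.ModelSpec` into a
:class:`Network` with seeded Glorot weights; the same seed yields
bit-identical initial weights and training trajectory on the same machine.
Training minimises categorical cross-entropy (softmax fused into the loss
gradient) with mini-batch Adam, optionally early-stopping on a held-out
validation split with best-weight restoration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import layers as L
from .spec import ModelSpec, propagate_shapes

__all__ = ["TrainConfig", "Network", "instantiate"]


@dataclass
class TrainConfig:
    """Optimiser and schedule parameters for one training run."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    early_stop_patience: int | None = None
    loss: str = "categorical_crossentropy"
    seed: int = 0
    validation_fraction: float = 0.1  # carved from training data when patience is set

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("learning_rate, batch_size and max_epochs must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "categorical_crossentropy":
            raise ValueError(f"unsupported loss {self.loss!r}")


class _Adam:
    def __init__(self, params, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def instantiate(spec: ModelSpec, seed: int = 0, dtype=np.float32) -> "Network":
    """Build a trainable network from a layer-graph spec with seeded init."""
    shapes = [tuple(spec.input_shape)] + propagate_shapes(spec)
    rng = np.random.default_rng(seed)
    built: list[L.Layer] = []
    first_conv_seen = False
    for layer, shape_in in zip(spec.layers, shapes):
        if layer.kind == "conv2d":
            built.append(
                L.Conv2D(layer.kernel, layer.filters, layer.stride or (1, 1), shape_in[2],
                         layer.activation, rng, dtype=dtype, need_input_grad=first_conv_seen)
            )
            first_conv_seen = True
        elif layer.kind == "maxpool2d":
            built.append(L.MaxPool2D(layer.kernel))
            first_conv_seen = True
        elif layer.kind == "flatten":
            built.append(L.Flatten())
        elif layer.kind == "dropout":
            built.append(L.Dropout(layer.rate, rng))
        elif layer.kind == "dense":
            act = None if layer.activation == "softmax" else layer.activation
            built.append(L.Dense(shape_in[0], layer.units, act, rng, dtype=dtype))
    return Network(spec, built, rng, dtype)


class Network:
    """A feed-forward stack with softmax cross-entropy training."""

    def __init__(self, spec: ModelSpec, built: list[L.Layer], rng: np.random.Generator, dtype):
        self.spec = spec
        self.layers = built
        self.rng = rng
        self.dtype = dtype
        self.trained = False
        self.history: dict[str, list[float]] = {"loss": [], "val_loss": []}

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim == 3:  # add depth axis: (N, H, W) -> (N, H, W, 1)
            X = X[..., None]
        expect = tuple(self.spec.input_shape)
        if X.shape[1:] != expect:
            raise ValueError(f"input shape {X.shape[1:]} != model input {expect}")
        return X

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        out = self._prepare(X)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X)
        chunks = [
            _softmax(self.forward(X[i : i + batch_size], train=False).astype(np.float64))
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    def _loss_and_grad(self, X, y_onehot):
        logits = self.forward(X, train=True)
        probs = _softmax(logits.astype(np.float64))
        n = X.shape[0]
        loss = -np.sum(y_onehot * np.log(probs + 1e-12)) / n
        dlogits = ((probs - y_onehot) / n).astype(self.dtype)
        dout = dlogits
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return loss

    def evaluate_loss(self, X, y_onehot, batch_size: int = 256) -> float:
        total, n = 0.0, X.shape[0]
        for i in range(0, n, batch_size):
            probs = self.predict_proba(X[i : i + batch_size], batch_size)
            total += -np.sum(y_onehot[i : i + batch_size] * np.log(probs + 1e-12))
        return total / n

    def fit(self, X: np.ndarray, y: np.ndarray, config: TrainConfig,
            verbose: bool = False) -> "Network":
        """Train with mini-batch Adam.

        ``y`` is integer class ids in ``[0, class_count)``.  When
        ``early_stop_patience`` is set, ``validation_fraction`` of the data
        (stratified shuffle) is held out, validation loss is monitored and
        the best weights are restored at the end.
        """
        X = np.asarray(X)
        y = np.asarray(y, dtype=np.int64)
        K = self.spec.class_count
        onehot = np.eye(K, dtype=np.float64)[y]
        rng = np.random.default_rng(config.seed)

        X_val = y_val_onehot = None
        if config.early_stop_patience is not None and config.validation_fraction > 0:
            idx = rng.permutation(X.shape[0])
            n_val = max(1, int(round(config.validation_fraction * X.shape[0])))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            X_val, y_val_onehot = X[val_idx], onehot[val_idx]
            X, onehot = X[tr_idx], onehot[tr_idx]

        opt = _Adam(self.params, self.grads, config.learning_rate)
        best_val, best_params, wait = np.inf, None, 0
        n = X.shape[0]
        for epoch in range(config.max_epochs):
            order = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for i in range(0, n, config.batch_size):
                batch = order[i : i + config.batch_size]
                loss = self._loss_and_grad(X[batch], onehot[batch])
                opt.step()
                epoch_loss += loss * len(batch)
                seen += len(batch)
            self.history["loss"].append(epoch_loss / seen)
            if X_val is not None:
                val_loss = self.evaluate_loss(X_val, y_val_onehot)
                self.history["val_loss"].append(val_loss)
                if val_loss < best_val - 1e-6:
                    best_val, wait = val_loss, 0
                    best_params = [p.copy() for p in self.params]
                else:
                    wait += 1
                    if wait >= config.early_stop_patience:
                        break
            if verbose:
                msg = f"epoch {epoch + 1}: loss={self.history['loss'][-1]:.4f}"
                if X_val is not None:
                    msg += f" val_loss={self.history['val_loss'][-1]:.4f}"
                print(msg)
        if best_params is not None:
            for p, bp in zip(self.params, best_params):
                p[...] = bp
        self.trained = True
        return self

    # --- persistence -----------------------------------------------------
    def save_weights(self, path) -> None:
        np.savez(path, **{f"p{i}": p for i, p in enumerate(self.params)})

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            for i, p in enumerate(self.params):
                p[...] = data[f"p{i}"]
        self.trained = True
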
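"""Architecture builders for the two graph-embedding classifiers and the
ablation baselines, plus first-layer feature-map export.

Adj-CNNM (structural route): one wide convolution whose kernel height
equals the channel count, so every filter sees all electrodes at once over
a 45-sample window, followed by aggressive temporal max-pooling::

    Conv2D (22, 45) x 64, stride (2, 2), ReLU
    MaxPool2D (1, 50)
    Flatten -> Dropout 0.25 -> Dense softmax

PLV-CNNM (functional route): a small 2-D CNN over the channels-by-channels
PLV matrix::

    Conv2D (3, 3) x 32, ReLU -> MaxPool2D (2, 2) -> Conv2D (3, 3) x 64, ReLU
    Dropout 0.25 -> Flatten -> Dense softmax

Default training regimes differ: Adam lr 1e-4, batch 128, up to 1000
epochs with early stopping (patience 250) for the structural model; Adam
lr 1e-3, batch 64, 800 epochs, no early stopping for the functional one.
All padding is "valid" and pooling stride equals the pool size.
"""

from __future__ import annotations

import warnings

import numpy as np

from .nn import LayerSpec, ModelSpec, Network, TrainConfig

__all__ = [
    "build_adj_cnnm",
    "build_plv_cnnm",
    "build_ablation_baseline",
    "default_train_config",
    "export_feature_maps",
]

ABLATIONS = ("no_adj_graph", "no_plv_graph")


def build_adj_cnnm(input_shape=(22, 1000, 1), class_count: int = 4, *,
                   filters: int = 64, kernel_width: int = 45, kernel_height: int = 22,
                   stride=(2, 2), pool=(1, 50), dropout: float = 0.25) -> ModelSpec:
    """Structural-route architecture; kernel height must equal input height."""
    H, W, C = input_shape
    if kernel_height != H:
        raise ValueError(
            f"conv kernel height {kernel_height} must equal input height {H} "
            "(the first layer spans all channels at once)"
        )
    spec = ModelSpec(
        name="adj-cnnm",
        input_shape=(H, W, C),
        layers=(
            LayerSpec("conv2d", kernel=(H, kernel_width), filters=filters,
                      stride=tuple(stride), activation="relu"),
            LayerSpec("maxpool2d", kernel=tuple(pool)),
            LayerSpec("flatten"),
            LayerSpec("dropout", rate=dropout),
            LayerSpec("dense", units=class_count, activation="softmax"),
        ),
        class_count=class_count,
    )
    spec.output_shapes()  # validates chaining (kernel vs input, etc.)
    return spec


def build_plv_cnnm(input_shape=(22, 22, 1), class_count: int = 4, *,
                   filters=(32, 64), kernel=(3, 3), pool=(2, 2),
                   dropout: float = 0.25) -> ModelSpec:
    """Functional-route architecture over a square connectivity matrix."""
    H, W, C = input_shape
    if H != W:
        raise ValueError(f"PLV input must be square channels x channels, got ({H}, {W})")
    f1, f2 = filters
    spec = ModelSpec(
        name="plv-cnnm",
        input_shape=(H, W, C),
        layers=(
            LayerSpec("conv2d", kernel=tuple(kernel), filters=f1, stride=(1, 1), activation="relu"),
            LayerSpec("maxpool2d", kernel=tuple(pool)),
            LayerSpec("conv2d", kernel=tuple(kernel), filters=f2, stride=(1, 1), activation="relu"),
            LayerSpec("dropout", rate=dropout),
            LayerSpec("flatten"),
            LayerSpec("dense", units=class_count, activation="softmax"),
        ),
        class_count=class_count,
    )
    spec.output_shapes()
    return spec


def build_ablation_baseline(which: str, input_shape=(22, 1000, 1),
                            class_count: int = 4) -> ModelSpec:
    """Baselines with the graph representation removed.

    ``no_adj_graph``: the structural architecture fed raw (unembedded)
    trials — the layer graph is identical; only the input preprocessing
    differs.  ``no_plv_graph``: the functional architecture re-targeted at
    raw band-passed trials; the first kernel is widened to (3, 45) to give
    a comparable temporal receptive field and parameter count (the
    original consumes 22x22 matrices, which do not exist without PLV).
    """
    if which == "no_adj_graph":
        spec = build_adj_cnnm(input_shape, class_count)
        return ModelSpec(name="cnn-no-adj-graph", input_shape=spec.input_shape,
                         layers=spec.layers, class_count=class_count)
    if which == "no_plv_graph":
        H, W, C = input_shape
        spec = ModelSpec(
            name="cnn-no-plv-graph",
            input_shape=(H, W, C),
            layers=(
                LayerSpec("conv2d", kernel=(3, 45), filters=32, stride=(1, 1), activation="relu"),
                LayerSpec("maxpool2d", kernel=(2, 2)),
                LayerSpec("conv2d", kernel=(3, 3), filters=64, stride=(1, 1), activation="relu"),
                LayerSpec("dropout", rate=0.25),
                LayerSpec("flatten"),
                LayerSpec("dense", units=class_count, activation="softmax"),
            ),
            class_count=class_count,
        )
        spec.output_shapes()
        return spec
    raise ValueError(f"unknown ablation {which!r}; available: {', '.join(ABLATIONS)}")


def default_train_config(model_name: str, seed: int = 0) -> TrainConfig:
    """The documented default training regime for each architecture."""
    if model_name in ("adj-cnnm", "cnn-no-adj-graph"):
        return TrainConfig(learning_rate=1e-4, batch_size=128, max_epochs=1000,
                           early_stop_patience=250, seed=seed)
    if model_name in ("plv-cnnm", "cnn-no-plv-graph"):
        return TrainConfig(learning_rate=1e-3, batch_size=64, max_epochs=800,
                           early_stop_patience=None, seed=seed)
    raise ValueError(f"no default training config for model {model_name!r}")


def export_feature_maps(network: Network, X: np.ndarray) -> np.ndarray:
    """First convolutional layer activations, ``(n, out_h, out_w, n_kernels)``.

    Enables numeric inspection of which input rows (channels) each learned
    kernel responds to.  Emits a warning (but still exports) when the
    network has not been trained.
    """
    if not network.trained:
        warnings.warn("exporting feature maps from an untrained network", stacklevel=2)
    from .nn.layers import Conv2D

    x = network._prepare(np.asarray(X))
    for layer in network.layers:
        out = layer.forward(x, train=False)
        if isinstance(layer, Conv2D):
            return np.asarray(out, dtype=np.float64)
        x = out
    raise ValueError("network has no convolutional layer")


def feature_maps_to_csv(maps: np.ndarray, path, channel_names=None) -> None:
    """Write kernel-averaged activations as a CSV table (kernels x positions)."""
    import pandas as pd

    mean_over_trials = maps.mean(axis=0)  # (out_h, out_w, F)
    F = mean_over_trials.shape[-1]
    table = mean_over_trials.reshape(-1, F).T  # kernels x spatial positions
    df = pd.DataFrame(table, index=[f"kernel_{k}" for k in range(F)])
    df.to_csv(path)
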
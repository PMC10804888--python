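"""Framework-independent layer-graph descriptions with symbolic shape propagation.

A :class:`ModelSpec` is an ordered list of :class:`LayerSpec` entries plus an
input shape ``(height, width, depth)`` and a class count.  Shapes chain with
"valid" (no padding) arithmetic:

    conv:  out = floor((in - kernel) / stride) + 1   per spatial axis
    pool:  out = floor(in / pool)                    (stride = pool size)

:func:`propagate_shapes` validates the chain and returns every intermediate
shape, so architectures can be checked without instantiating weights.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

__all__ = ["LayerSpec", "ModelSpec", "propagate_shapes"]

_KINDS = {"conv2d", "maxpool2d", "flatten", "dropout", "dense"}


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    kernel: tuple[int, int] | None = None   # conv2d / maxpool2d
    filters: int | None = None              # conv2d
    stride: tuple[int, int] | None = None   # conv2d (pool stride = pool size)
    activation: str | None = None           # "relu" | "softmax" | None
    rate: float | None = None               # dropout
    units: int | None = None                # dense

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    name: str
    input_shape: tuple[int, int, int]  # (height, width, depth)
    layers: tuple[LayerSpec, ...]
    class_count: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, payload: str) -> "ModelSpec":
        d = json.loads(payload)
        layers = tuple(
            LayerSpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in ld.items()})
            for ld in d["layers"]
        )
        return cls(name=d["name"], input_shape=tuple(d["input_shape"]),
                   layers=layers, class_count=d["class_count"])

    def output_shapes(self) -> list[tuple]:
        return propagate_shapes(self)


def propagate_shapes(spec: ModelSpec) -> list[tuple]:
    """Validate a spec and return the output shape after every layer.

    Spatial shapes are ``(H, W, C)`` tuples; after flatten they are ``(n,)``.
    Raises ``ValueError`` on any inconsistent chaining (e.g. kernel larger
    than its input, dense before flatten).
    """
    shape: tuple = tuple(spec.input_shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"bad input shape {shape}")
    out: list[tuple] = []
    for i, layer in enumerate(spec.layers):
        if layer.kind == "conv2d":
            if len(shape) != 3:
                raise ValueError(f"layer {i}: conv2d needs a spatial input, got {shape}")
            kh, kw = layer.kernel
            sh, sw = layer.stride or (1, 1)
            H, W, _ = shape
            if kh > H or kw > W:
                raise ValueError(
                    f"layer {i}: kernel ({kh}, {kw}) exceeds input ({H}, {W})"
                )
            shape = ((H - kh) // sh + 1, (W - kw) // sw + 1, layer.filters)
        elif layer.kind == "maxpool2d":
            if len(shape) != 3:
                raise ValueError(f"layer {i}: maxpool2d needs a spatial input, got {shape}")
            ph, pw = layer.kernel
            H, W, C = shape
            if H // ph < 1 or W // pw < 1:
                raise ValueError(f"layer {i}: pool ({ph}, {pw}) exceeds input ({H}, {W})")
            shape = (H // ph, W // pw, C)
        elif layer.kind == "flatten":
            if len(shape) != 3:
                raise ValueError(f"layer {i}: flatten needs a spatial input, got {shape}")
            shape = (shape[0] * shape[1] * shape[2],)
        elif layer.kind == "dropout":
            pass  # shape preserved
        elif layer.kind == "dense":
            if len(shape) != 1:
                raise ValueError(f"layer {i}: dense needs a flat input, got {shape}")
            shape = (layer.units,)
        out.append(shape)
    if not spec.layers or spec.layers[-1].kind != "dense":
        raise ValueError("spec must end with a dense layer")
    if out[-1] != (spec.class_count,):
        raise ValueError(f"final layer emits {out[-1]}, expected ({spec.class_count},)")
    return out
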
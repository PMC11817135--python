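"""CNN building blocks and the reference day-image architecture.

The primitives here are the arithmetic the network is made of: valid
convolution output sizing (an input extent K filtered by a kernel extent L
leaves K - L + 1 placements), the rectified linear unit, sliding-window max
pooling, and the softmax map from scores to class probabilities.

The reference architecture classifies a 30 (height) x 48 (width) x 1
day-image into three classes: three blocks of [conv 48 filters 3x3 (valid)
-> ReLU -> max-pool 3x3 stride 2], then flatten and a fully connected head
900 -> 300 -> 100 -> 3 with ReLU + dropout between the dense layers and a
softmax output.  The shape trace is
30x48 -> 28x46 -> 13x22 -> 11x20 -> 5x9 -> 3x7 -> 1x3 -> flatten 144.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path

import numpy as np
import yaml

from .preprocess import IMAGE_SHAPE


class LayerKind(str, enum.Enum):
    CONV = "conv"
    RELU = "relu"
    MAXPOOL = "maxpool"
    DROPOUT = "dropout"
    FLATTEN = "flatten"
    DENSE = "dense"
    SOFTMAX = "softmax"


@dataclasses.dataclass
class LayerSpec:
    """Description of one layer; only the fields relevant to ``kind`` are set."""

    kind: LayerKind
    filters: int | None = None  # conv: number of kernels
    kernel: int | None = None  # conv/maxpool: square window extent
    stride: int = 1
    padding: int = 0
    width: int | None = None  # dense: output size
    rate: float | None = None  # dropout rate in [0, 1)

    def __post_init__(self) -> None:
        self.kind = LayerKind(self.kind)
        if self.kernel is not None and self.kernel < 1:
            raise ValueError("kernel extent must be positive")
        if self.stride < 1:
            raise ValueError("stride must be positive")
        if self.rate is not None and not 0 <= self.rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")


@dataclasses.dataclass
class ShapeTrace:
    """Per-layer output shapes of an architecture on a given input."""

    entries: list[tuple[str, tuple[int, ...]]]
    flattened: int | None = None


@dataclasses.dataclass
class ArchitectureSpec:
    """An ordered stack of layers over a fixed input shape."""

    layers: list[LayerSpec]
    input_shape: tuple[int, int, int] = (*IMAGE_SHAPE, 1)
    num_classes: int = 3

    def validate(self) -> ShapeTrace:
        """Check the stack is consistent: traceable end to end, softmax head."""
        if not self.layers or self.layers[-1].kind is not LayerKind.SOFTMAX:
            raise ValueError("final layer must be softmax")
        dense = [l for l in self.layers if l.kind is LayerKind.DENSE]
        if not dense or dense[-1].width != self.num_classes:
            raise ValueError("last dense layer must emit num_classes scores")
        return trace_shapes(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = {
            "input_shape": list(self.input_shape),
            "num_classes": self.num_classes,
            "layers": [
                {
                    k: (v.value if isinstance(v, LayerKind) else v)
                    for k, v in dataclasses.asdict(layer).items()
                    if v is not None
                }
                for layer in self.layers
            ],
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ArchitectureSpec":
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        doc = yaml.safe_load(text)
        layers = [LayerSpec(**{"stride": 1, "padding": 0, **d}) for d in doc["layers"]]
        return cls(
            layers=layers,
            input_shape=tuple(doc["input_shape"]),
            num_classes=doc["num_classes"],
        )


def conv_output_size(K: int, L: int) -> int:
    """Output extent of a valid, stride-1 convolution: K - L + 1.

    This counts the placements of a length-L kernel inside a length-K input.
    """
    if L < 1:
        raise ValueError("kernel extent must be at least 1")
    if L > K:
        raise ValueError(f"kernel extent {L} exceeds input extent {K}")
    return K - L + 1


def pool_output_size(K: int, k: int, s: int, p: int = 0) -> int:
    """Output extent of a k-window, stride-s pooling with padding p."""
    if k > K + 2 * p:
        raise ValueError(f"pooling window {k} exceeds padded input {K + 2 * p}")
    return (K + 2 * p - k) // s + 1


def relu(x):
    """Elementwise rectifier: max(0, x)."""
    return np.maximum(0, np.asarray(x))


def max_pool(feature_map, k: int, s: int = 1, p: int = 0) -> np.ndarray:
    """Max pooling of a 2-D feature map with a k x k window and stride s.

    The input is zero-padded by ``p`` on every side; each output cell is the
    maximum over its window.
    """
    x = np.asarray(feature_map, dtype=float)
    if x.ndim != 2:
        raise ValueError("feature map must be 2-D")
    if k < 1 or s < 1:
        raise ValueError("window and stride must be positive")
    if p:
        x = np.pad(x, p)
    H, W = x.shape
    Ho = pool_output_size(H, k, s, 0)
    Wo = pool_output_size(W, k, s, 0)
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k))[::s, ::s]
    return windows[:Ho, :Wo].max(axis=(2, 3))


def softmax(z, axis: int = -1) -> np.ndarray:
    """Scores to probabilities: exp(z_i) / sum_j exp(z_j), computed stably."""
    z = np.asarray(z, dtype=float)
    shifted = z - z.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def trace_shapes(
    arch: ArchitectureSpec, input_hw: tuple[int, int] | None = None
) -> ShapeTrace:
    """Walk the architecture computing every layer's output shape.

    Raises on impossible configurations (a kernel or window larger than its
    input, a dense layer before flattening), naming the offending layer.
    """
    if input_hw is None:
        h, w = arch.input_shape[:2]
        c = arch.input_shape[2] if len(arch.input_shape) > 2 else 1
    else:
        h, w = input_hw
        c = 1
    shape: tuple[int, ...] = (h, w, c)
    flat: int | None = None
    entries: list[tuple[str, tuple[int, ...]]] = [("input", shape)]
    for i, layer in enumerate(arch.layers):
        name = f"{layer.kind.value}_{i}"
        try:
            if layer.kind is LayerKind.CONV:
                if flat is not None:
                    raise ValueError("conv after flatten")
                if layer.stride != 1:
                    raise ValueError("convolution is defined for stride 1")
                h2 = conv_output_size(shape[0] + 2 * layer.padding, layer.kernel)
                w2 = conv_output_size(shape[1] + 2 * layer.padding, layer.kernel)
                shape = (h2, w2, layer.filters)
            elif layer.kind is LayerKind.MAXPOOL:
                if flat is not None:
                    raise ValueError("pool after flatten")
                h2 = pool_output_size(shape[0], layer.kernel, layer.stride, layer.padding)
                w2 = pool_output_size(shape[1], layer.kernel, layer.stride, layer.padding)
                shape = (h2, w2, shape[2])
            elif layer.kind is LayerKind.FLATTEN:
                flat = int(np.prod(shape))
                shape = (flat,)
            elif layer.kind is LayerKind.DENSE:
                if len(shape) != 1:
                    raise ValueError("dense requires a flattened input")
                shape = (layer.width,)
            # relu/dropout/softmax preserve shape
            if any(d <= 0 for d in shape):
                raise ValueError("non-positive extent")
        except ValueError as exc:
            raise ValueError(f"layer {name}: {exc}") from exc
        entries.append((name, shape))
    return ShapeTrace(entries=entries, flattened=flat)


def build_reference_architecture(
    *,
    dropout_rate: float = 0.5,
    conv_dropout: bool = False,
    conv_padding: int = 0,
    pool_kernel: int = 3,
    pool_stride: int = 2,
    num_filters: int = 48,
    dense_widths: tuple[int, ...] = (900, 300, 100),
    num_classes: int = 3,
    input_shape: tuple[int, int, int] = (*IMAGE_SHAPE, 1),
) -> ArchitectureSpec:
    """The reference day-image classifier.

    Defaults give the reconciled geometry (valid convolutions, 3x3/stride-2
    pooling, three dense hidden layers with dropout, softmax over 3 classes);
    every knob is exposed so alternative consistent geometries can be forced.
    ``conv_dropout`` adds dropout after the first two pooling stages, for a
    total of five dropout layers.
    """
    layers: list[LayerSpec] = []
    for block in range(3):
        layers.append(
            LayerSpec(
                LayerKind.CONV, filters=num_filters, kernel=3, padding=conv_padding
            )
        )
        layers.append(LayerSpec(LayerKind.RELU))
        layers.append(
            LayerSpec(LayerKind.MAXPOOL, kernel=pool_kernel, stride=pool_stride)
        )
        if conv_dropout and block < 2:
            layers.append(LayerSpec(LayerKind.DROPOUT, rate=dropout_rate))
    layers.append(LayerSpec(LayerKind.FLATTEN))
    for width in dense_widths:
        layers.append(LayerSpec(LayerKind.DENSE, width=width))
        layers.append(LayerSpec(LayerKind.RELU))
        layers.append(LayerSpec(LayerKind.DROPOUT, rate=dropout_rate))
    layers.append(LayerSpec(LayerKind.DENSE, width=num_classes))
    layers.append(LayerSpec(LayerKind.SOFTMAX))
    arch = ArchitectureSpec(
        layers=layers, input_shape=input_shape, num_classes=num_classes
    )
    arch.validate()
    return arch
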
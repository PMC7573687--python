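"""Declarative layer-by-layer model descriptions and parameter counting.

A :class:`ModelSpec` is a backend-independent description of a network that is
sufficient both to count parameters and to instantiate a trainable network.
The counting convention matches the one used by common deep-learning
frameworks: a convolution contributes ``k*k*c_in*c_out`` weights plus ``c_out``
biases, a dense layer ``n_in*n_out + n_out``, and a batch-normalisation layer
4 parameters per channel (scale, shift and the two moving statistics).
Activations, flatten and pooling layers contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Conv2D",
    "BatchNorm",
    "Activation",
    "MaxPool2D",
    "Flatten",
    "Dense",
    "ModelSpec",
    "count_parameters",
]


@dataclass(frozen=True)
class Conv2D:
    kernel_size: int
    in_channels: int
    out_channels: int
    stride: int = 1
    padding: str = "same"  # "same" or "valid"
    bias: bool = True

    @property
    def n_parameters(self) -> int:
        n = self.kernel_size * self.kernel_size * self.in_channels * self.out_channels
        return n + (self.out_channels if self.bias else 0)


@dataclass(frozen=True)
class BatchNorm:
    channels: int

    @property
    def n_parameters(self) -> int:
        # scale, shift, moving mean, moving variance
        return 4 * self.channels


@dataclass(frozen=True)
class Activation:
    kind: str  # "leaky_relu" or "softmax"
    alpha: float = 0.01

    n_parameters: int = field(default=0, init=False)


@dataclass(frozen=True)
class MaxPool2D:
    pool_size: int = 2

    n_parameters: int = field(default=0, init=False)


@dataclass(frozen=True)
class Flatten:
    n_parameters: int = field(default=0, init=False)


@dataclass(frozen=True)
class Dense:
    in_features: int
    out_features: int
    bias: bool = True

    @property
    def n_parameters(self) -> int:
        n = self.in_features * self.out_features
        return n + (self.out_features if self.bias else 0)


Layer = Conv2D | BatchNorm | Activation | MaxPool2D | Flatten | Dense


def _conv_out(size: int, kernel: int, stride: int, padding: str) -> int:
    if padding == "same":
        return -(-size // stride)  # ceil
    if padding == "valid":
        return (size - kernel) // stride + 1
    raise ValueError(f"unknown padding {padding!r}")


@dataclass(frozen=True)
class ModelSpec:
    """An ordered stack of layer descriptors with a fixed input shape."""

    layers: tuple[Layer, ...]
    input_shape: tuple[int, int, int] = (64, 64, 3)
    name: str = ""

    def __post_init__(self) -> None:
        self.infer_shapes()  # raises on inconsistency

    def infer_shapes(self) -> list[tuple[int, ...]]:
        """Propagate the input shape through the stack, validating consistency.

        Returns the list of output shapes, one per layer.  Spatial shapes are
        (H, W, C); after flatten, shapes are (n_features,).
        """
        shape: tuple[int, ...] = self.input_shape
        out: list[tuple[int, ...]] = []
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Conv2D):
                if len(shape) != 3 or shape[2] != layer.in_channels:
                    raise ValueError(
                        f"layer {i} ({layer}): expects {layer.in_channels} input "
                        f"channels, upstream shape is {shape}"
                    )
                h = _conv_out(shape[0], layer.kernel_size, layer.stride, layer.padding)
                w = _conv_out(shape[1], layer.kernel_size, layer.stride, layer.padding)
                shape = (h, w, layer.out_channels)
            elif isinstance(layer, BatchNorm):
                if shape[-1] != layer.channels:
                    raise ValueError(
                        f"layer {i} ({layer}): expects {layer.channels} channels, "
                        f"upstream shape is {shape}"
                    )
            elif isinstance(layer, MaxPool2D):
                if len(shape) != 3:
                    raise ValueError(f"layer {i}: max-pool needs a spatial input")
                shape = (shape[0] // layer.pool_size, shape[1] // layer.pool_size, shape[2])
            elif isinstance(layer, Flatten):
                shape = (int(_prod(shape)),)
            elif isinstance(layer, Dense):
                if len(shape) != 1 or shape[0] != layer.in_features:
                    raise ValueError(
                        f"layer {i} ({layer}): expects {layer.in_features} features, "
                        f"upstream shape is {shape}"
                    )
                shape = (layer.out_features,)
            elif isinstance(layer, Activation):
                pass
            else:  # pragma: no cover
                raise TypeError(f"unknown layer type {type(layer)}")
            out.append(shape)
        return out

    @property
    def output_shape(self) -> tuple[int, ...]:
        return self.infer_shapes()[-1]


def _prod(shape: tuple[int, ...]) -> int:
    n = 1
    for s in shape:
        n *= s
    return n


def count_parameters(spec: ModelSpec) -> int:
    """Total parameter count: weights, biases and batch-norm moving statistics."""
    spec.infer_shapes()
    return sum(layer.n_parameters for layer in spec.layers)
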
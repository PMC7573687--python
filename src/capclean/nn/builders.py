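"""Builders for the patch-classification architectures.

Two architectures share the same classification head (flatten, a 128-unit
dense layer with LeakyReLU and batch normalisation, and a 2-unit softmax
layer):

* the light-weight network designed for intestinal-content classification —
  four convolutional blocks, each closed by a stride-2 convolution in place of
  pooling, totalling 1,708,610 parameters at full width;
* a VGG-16 comparator — the standard 13-convolution base on a 64x64x3 input
  (output 2x2x512) plus the shared head, totalling 14,977,730 parameters.
"""

from __future__ import annotations

from .spec import Activation, BatchNorm, Conv2D, Dense, Flatten, MaxPool2D, ModelSpec

__all__ = ["PROPOSED_CHANNELS", "build_proposed_cnn", "build_vgg16_classifier"]

# Per-convolution output channels of the full-width network, in order:
# block 1 (conv, conv, strided conv), blocks 2-4 (conv, strided conv).
PROPOSED_CHANNELS = (48, 48, 48, 64, 64, 96, 128, 192, 320)

_LEAKY_ALPHA = 0.01


def _conv_block_layer(c_in: int, c_out: int, stride: int) -> list:
    return [
        Conv2D(kernel_size=3, in_channels=c_in, out_channels=c_out, stride=stride),
        Activation("leaky_relu", alpha=_LEAKY_ALPHA),
        BatchNorm(c_out),
    ]


def _head(flat_features: int) -> list:
    return [
        Flatten(),
        Dense(flat_features, 128),
        Activation("leaky_relu", alpha=_LEAKY_ALPHA),
        BatchNorm(128),
        Dense(128, 2),
        Activation("softmax"),
    ]


def build_proposed_cnn(width_multiplier: float = 1.0) -> ModelSpec:
    """Build the light-weight patch classifier.

    Block 1 has two stride-1 convolutions followed by a stride-2 convolution;
    blocks 2-4 have one stride-1 convolution followed by a stride-2
    convolution.  All convolutions are 3x3 with LeakyReLU activation and batch
    normalisation; there is no pooling and no dropout.  Four stride-2 layers
    reduce a 64x64 input to 4x4 before the head.

    ``width_multiplier`` scales every convolution's channel count (rounded,
    minimum 1), so a reduced variant can be trained quickly on a CPU; at 1.0
    the total parameter count is 1,708,610.
    """
    if width_multiplier <= 0:
        raise ValueError("width_multiplier must be positive")
    ch = [max(1, round(c * width_multiplier)) for c in PROPOSED_CHANNELS]
    strides = (1, 1, 2, 1, 2, 1, 2, 1, 2)
    layers: list = []
    c_in = 3
    for c_out, stride in zip(ch, strides):
        layers += _conv_block_layer(c_in, c_out, stride)
        c_in = c_out
    layers += _head(4 * 4 * ch[-1])
    return ModelSpec(tuple(layers), input_shape=(64, 64, 3), name="proposed")


_VGG16_CFG = (64, 64, "M", 128, 128, "M", 256, 256, 256, "M", 512, 512, 512, "M",
              512, 512, 512, "M")


def build_vgg16_classifier() -> ModelSpec:
    """Build the VGG-16 comparator: standard conv base plus the shared head.

    The base has 13 3x3 convolutions (ReLU in the original; LeakyReLU here for
    head parity — activation choice does not affect the parameter count) and
    five 2x2 max-pools, mapping 64x64x3 to 2x2x512.  The head is the shared
    flatten(2048) -> dense(128)+LeakyReLU+BN -> dense(2)+softmax stack.
    """
    layers: list = []
    c_in = 3
    for item in _VGG16_CFG:
        if item == "M":
            layers.append(MaxPool2D(2))
        else:
            layers.append(Conv2D(kernel_size=3, in_channels=c_in, out_channels=item))
            layers.append(Activation("leaky_relu", alpha=_LEAKY_ALPHA))
            c_in = item
    layers += _head(2 * 2 * 512)
    return ModelSpec(tuple(layers), input_shape=(64, 64, 3), name="vgg16")
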
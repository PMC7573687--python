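"""A compact numpy network runtime instantiated from a :class:`ModelSpec`.

Implements exactly the layer vocabulary the patch classifiers need —
convolution (stride 1 or 2, "same"/"valid" padding), batch normalisation,
LeakyReLU, max-pooling, flatten, dense and softmax — with reverse-mode
gradients throughout.  Convolutions are computed as a sum over the k*k kernel
offsets of strided-slice matrix products, which keeps both the forward and the
backward pass inside BLAS without materialising an im2col buffer.

Training uses the 2-class softmax cross-entropy; the softmax and the loss are
fused, so the backward pass is seeded at the logits with ``(p - y)/N``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import spec as S

__all__ = ["Network"]


def _same_pad(size: int, kernel: int, stride: int) -> tuple[int, int]:
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    return total // 2, total - total // 2


class _Layer:
    """Runtime layer base: parameter arrays live in ``params`` (name -> array)."""

    trainable_names: tuple[str, ...] = ()

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_parameters(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.params.values())


class _Conv2D(_Layer):
    trainable_names = ("W", "b")

    def __init__(self, d: S.Conv2D, rng: np.random.Generator) -> None:
        super().__init__()
        self.d = d
        k, cin, cout = d.kernel_size, d.in_channels, d.out_channels
        scale = np.sqrt(2.0 / (k * k * cin))  # He initialisation
        self.params["W"] = (rng.standard_normal((k, k, cin, cout)) * scale).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        d = self.d
        n, h, w, _ = x.shape
        if d.padding == "same":
            pt, pb = _same_pad(h, d.kernel_size, d.stride)
            pl, pr = _same_pad(w, d.kernel_size, d.stride)
            xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
            self._pads = (pt, pb, pl, pr)
        else:
            xp = x
            self._pads = (0, 0, 0, 0)
        ho = _conv_out_size(h, d.kernel_size, d.stride, d.padding)
        wo = _conv_out_size(w, d.kernel_size, d.stride, d.padding)
        W, b = self.params["W"], self.params["b"]
        out = np.empty((n, ho, wo, d.out_channels), dtype=np.float32)
        out[:] = b
        flat = out.reshape(-1, d.out_channels)
        s = d.stride
        for i in range(d.kernel_size):
            for j in range(d.kernel_size):
                xs = xp[:, i : i + s * ho : s, j : j + s * wo : s, :]
                flat += xs.reshape(-1, d.in_channels) @ W[i, j]
        self._cache = (xp, x.shape, ho, wo)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.d
        xp, x_shape, ho, wo = self._cache
        n = x_shape[0]
        s = d.stride
        W = self.params["W"]
        dflat = dout.reshape(-1, d.out_channels)
        self.grads["b"] = dout.sum(axis=(0, 1, 2))
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        for i in range(d.kernel_size):
            for j in range(d.kernel_size):
                xs = xp[:, i : i + s * ho : s, j : j + s * wo : s, :]
                dW[i, j] = xs.reshape(-1, d.in_channels).T @ dflat
                dxp[:, i : i + s * ho : s, j : j + s * wo : s, :] += (
                    dflat @ W[i, j].T
                ).reshape(n, ho, wo, d.in_channels)
        self.grads["W"] = dW
        pt, pb, pl, pr = self._pads
        h, w = x_shape[1], x_shape[2]
        return dxp[:, pt : pt + h, pl : pl + w, :]


def _conv_out_size(size: int, kernel: int, stride: int, padding: str) -> int:
    if padding == "same":
        return -(-size // stride)
    return (size - kernel) // stride + 1


class _BatchNorm(_Layer):
    """Channel-wise batch normalisation (last axis), eps 1e-3, momentum 0.9.

    The moving-statistics momentum is lower than the common 0.99 default so
    inference-mode statistics track the batch statistics within a few dozen
    steps; with the short training schedules this package targets, a 0.99
    average would still be dominated by its initialisation after an epoch.
    """

    trainable_names = ("gamma", "beta")
    EPS = 1e-3
    MOMENTUM = 0.9

    def __init__(self, d: S.BatchNorm) -> None:
        super().__init__()
        c = d.channels
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.params["moving_mean"] = np.zeros(c, dtype=np.float32)
        self.params["moving_var"] = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.MOMENTUM
            self.params["moving_mean"] = (m * self.params["moving_mean"] + (1 - m) * mean).astype(np.float32)
            self.params["moving_var"] = (m * self.params["moving_var"] + (1 - m) * var).astype(np.float32)
        else:
            mean = self.params["moving_mean"]
            var = self.params["moving_var"]
        inv_std = 1.0 / np.sqrt(var + self.EPS)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std, axes, x.shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, shape = self._cache
        m = 1
        for a in axes:
            m *= shape[a]
        gamma = self.params["gamma"]
        self.grads["beta"] = dout.sum(axis=axes)
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        dxhat = dout * gamma
        return (
            inv_std
            / m
            * (m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        ).astype(np.float32)


class _LeakyReLU(_Layer):
    def __init__(self, alpha: float) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x >= 0
        return np.where(x >= 0, x, self.alpha * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.alpha * dout)


class _Softmax(_Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise RuntimeError(
            "softmax backward is fused with the cross-entropy loss; "
            "seed the backward pass at the logits"
        )


class _MaxPool2D(_Layer):
    def __init__(self, d: S.MaxPool2D) -> None:
        super().__init__()
        self.p = d.pool_size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        p = self.p
        n, h, w, c = x.shape
        xr = x.reshape(n, h // p, p, w // p, p, c)
        out = xr.max(axis=(2, 4))
        if training:
            mask = xr == out[:, :, None, :, None, :]
            # split gradient evenly among ties so the pooling map stays exact
            self._mask = mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1)
            self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self._mask * dout[:, :, None, :, None, :]
        return d.reshape(self._shape).astype(np.float32)


class _Flatten(_Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class _Dense(_Layer):
    trainable_names = ("W", "b")

    def __init__(self, d: S.Dense, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / d.in_features)
        self.params["W"] = (
            rng.standard_normal((d.in_features, d.out_features)) * scale
        ).astype(np.float32)
        self.params["b"] = np.zeros(d.out_features, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def _build_layer(d, rng: np.random.Generator) -> _Layer:
    if isinstance(d, S.Conv2D):
        return _Conv2D(d, rng)
    if isinstance(d, S.BatchNorm):
        return _BatchNorm(d)
    if isinstance(d, S.Activation):
        return _Softmax() if d.kind == "softmax" else _LeakyReLU(d.alpha)
    if isinstance(d, S.MaxPool2D):
        return _MaxPool2D(d)
    if isinstance(d, S.Flatten):
        return _Flatten()
    if isinstance(d, S.Dense):
        return _Dense(d, rng)
    raise TypeError(f"unknown layer descriptor {type(d)}")


class Network:
    """A trainable network instantiated from a :class:`ModelSpec`."""

    def __init__(self, spec: S.ModelSpec, seed: int = 0) -> None:
        spec.infer_shapes()
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.layers: list[_Layer] = [_build_layer(d, rng) for d in spec.layers]
        self._has_softmax = isinstance(self.layers[-1], _Softmax)

    # -- parameters ---------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        """Total count over the instantiated arrays, moving statistics included."""
        return sum(layer.n_parameters for layer in self.layers)

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in layer.params.items()} for layer in self.layers]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for layer, w in zip(self.layers, weights):
            for k in layer.params:
                layer.params[k] = w[k].copy()

    def trainable_parameters(
        self, layer_indices: list[int] | None = None
    ) -> list[tuple[int, str]]:
        """(layer index, parameter name) pairs for the optimiser."""
        idx = range(len(self.layers)) if layer_indices is None else layer_indices
        return [
            (i, name)
            for i in idx
            for name in self.layers[i].trainable_names
        ]

    @property
    def head_start(self) -> int:
        """Index of the flatten layer, where the classification head begins."""
        for i, d in enumerate(self.spec.layers):
            if isinstance(d, S.Flatten):
                return i
        raise ValueError("spec has no flatten layer")

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def forward_logits(self, x: np.ndarray, training: bool, start: int = 0) -> np.ndarray:
        """Forward pass up to the logits, optionally starting mid-stack.

        Layers before ``start`` are skipped (the caller feeds their output),
        so a frozen base can be evaluated once outside the training loop.
        """
        out = np.asarray(x, dtype=np.float32)
        end = len(self.layers) - 1 if self._has_softmax else len(self.layers)
        for layer in self.layers[start:end]:
            out = layer.forward(out, training)
        return out

    def backward_from_logits(self, dlogits: np.ndarray, stop: int = 0) -> np.ndarray:
        """Backpropagate a gradient seeded at the logits (softmax fused away)."""
        grad = dlogits.astype(np.float32)
        end = len(self.layers) - 1 if self._has_softmax else len(self.layers)
        for layer in reversed(self.layers[stop:end]):
            grad = layer.backward(grad)
        return grad

    def forward_prefix(self, x: np.ndarray, end: int, batch_size: int = 256) -> np.ndarray:
        """Inference-mode forward through ``layers[:end]`` (frozen-base features)."""
        x = np.asarray(x, dtype=np.float32)
        outs = []
        for i in range(0, len(x), batch_size):
            out = x[i : i + batch_size]
            for layer in self.layers[:end]:
                out = layer.forward(out, training=False)
            outs.append(out)
        return np.concatenate(outs, axis=0)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities in inference mode, batched."""
        x = np.asarray(x, dtype=np.float32)
        outs = [
            self.forward(x[i : i + batch_size], training=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Save weights (.npz) with a JSON spec sidecar (.json)."""
        path = Path(path)
        arrays = {
            f"{i}/{k}": v
            for i, layer in enumerate(self.layers)
            for k, v in layer.params.items()
        }
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = [
            {"type": type(d).__name__, **{k: v for k, v in vars(d).items()}}
            for d in self.spec.layers
        ]
        path.with_suffix(".json").write_text(
            json.dumps({"input_shape": self.spec.input_shape, "layers": sidecar}, indent=1)
        )

    def load(self, path: str | Path) -> None:
        data = np.load(Path(path).with_suffix(".npz"))
        for key in data.files:
            i, name = key.split("/")
            self.layers[int(i)].params[name] = data[key]
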
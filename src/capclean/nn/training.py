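"""Training loops: mini-batch cross-entropy with keep-best checkpointing.

After every epoch the candidate model is accepted only if its validation
accuracy improved; the returned model is the best-on-validation one.  Training
stops early when no improvement is seen for ``patience`` epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network import Network
from .optim import make_optimizer
from .spec import ModelSpec

__all__ = ["HyperParams", "TrainingHistory", "train_model", "train_vgg_two_stage"]


@dataclass(frozen=True)
class HyperParams:
    batch_size: int = 16
    learning_rate: float = 0.0005
    optimizer: str = "nadam"  # "nadam" or "sgd"
    sgd_momentum: float = 0.9
    sgd_decay: float = 0.0
    max_epochs: int = 100
    patience: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def save(self, path) -> None:
        """Persist as flat JSON."""
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def load(cls, path) -> "HyperParams":
        import json
        from pathlib import Path

        return cls(**json.loads(Path(path).read_text()))


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_accuracy(self) -> float:
        return self.val_accuracy[self.best_epoch]


def _check_two_classes(y: np.ndarray) -> None:
    classes = np.unique(y)
    if len(y) == 0:
        raise ValueError("empty training set")
    if classes.size < 2:
        raise ValueError("training data must contain both classes")


def _accuracy(net: Network, x: np.ndarray, y: np.ndarray) -> float:
    probs = net.predict_proba(x)
    return float(np.mean(probs.argmax(axis=1) == y))


def _fit(
    net: Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    hp: HyperParams,
    frozen_prefix: int = 0,
) -> TrainingHistory:
    rng = np.random.default_rng(hp.seed)
    opt = make_optimizer(hp.optimizer, hp.learning_rate, hp.sgd_momentum, hp.sgd_decay)
    trainable = list(range(frozen_prefix, len(net.layers)))
    param_keys = net.trainable_parameters(trainable)
    history = TrainingHistory()
    best_acc = -np.inf
    best_weights = net.get_weights()
    n = len(x_train)
    x_train = np.asarray(x_train, dtype=np.float32)
    if frozen_prefix:
        # The frozen base is a fixed function: evaluate its features once.
        x_train = net.forward_prefix(x_train, frozen_prefix)
    y_onehot = np.eye(2, dtype=np.float32)[y_train]
    since_improve = 0
    for epoch in range(hp.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            xb, yb = x_train[idx], y_onehot[idx]
            logits = net.forward_logits(xb, training=True, start=frozen_prefix)
            z = logits - logits.max(axis=1, keepdims=True)
            logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
            losses.append(float(-(yb * logp).sum() / len(idx)))
            net.backward_from_logits((np.exp(logp) - yb) / len(idx), stop=frozen_prefix)
            params = [net.layers[i].params[k] for i, k in param_keys]
            grads = [net.layers[i].grads[k] for i, k in param_keys]
            opt.step(params, grads)
        acc = _accuracy(net, x_val, y_val)
        history.train_loss.append(float(np.mean(losses)))
        history.val_accuracy.append(acc)
        if acc > best_acc:
            best_acc = acc
            best_weights = net.get_weights()
            history.best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= hp.patience:
                break
    net.set_weights(best_weights)
    return history


def train_model(
    spec: ModelSpec | Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    hp: HyperParams | None = None,
) -> tuple[Network, TrainingHistory]:
    """Train a classifier; labels are 0 = clean, 1 = dirty.

    Returns the network restored to its best-on-validation weights, plus the
    per-epoch history.  Deterministic for a fixed ``hp.seed``.
    """
    hp = hp or HyperParams()
    _check_two_classes(np.asarray(y_train))
    net = spec if isinstance(spec, Network) else Network(spec, seed=hp.seed)
    history = _fit(net, x_train, np.asarray(y_train), x_val, np.asarray(y_val), hp)
    return net, history


def train_vgg_two_stage(
    net: Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    hp: HyperParams | None = None,
    stage1_epochs: int | None = None,
) -> tuple[Network, TrainingHistory, TrainingHistory]:
    """Two-stage fine-tuning: head only first, then the whole network.

    Stage 1 updates only the classification head (flatten onward), leaving the
    convolutional base untouched; stage 2 unfreezes everything.  The optimiser
    is SGD with momentum 0.9 and zero decay, as used for VGG fine-tuning.
    Pretrained base weights, when available, are loaded onto ``net`` before
    calling; with a randomly initialised base the procedure still runs.
    """
    hp = hp or HyperParams(optimizer="sgd")
    hp = replace(hp, optimizer="sgd")
    _check_two_classes(np.asarray(y_train))
    hp1 = hp if stage1_epochs is None else replace(hp, max_epochs=stage1_epochs)
    hist1 = _fit(net, x_train, np.asarray(y_train), x_val, np.asarray(y_val), hp1,
                 frozen_prefix=net.head_start)
    hist2 = _fit(net, x_train, np.asarray(y_train), x_val, np.asarray(y_val), hp)
    return net, hist1, hist2
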
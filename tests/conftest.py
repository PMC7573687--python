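import numpy as np
import pytest

from capclean.nn import HyperParams, build_proposed_cnn, train_model
from capclean.synthetic import generate_labeled_patches


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def patch_dataset():
    """~2,000 balanced synthetic patches split 70/15/15 train/val/test."""
    x, y = generate_labeled_patches(2000, seed=7)
    order = np.random.default_rng(0).permutation(len(x))
    x, y = x[order], y[order]
    n_train, n_val = int(0.7 * len(x)), int(0.85 * len(x))
    return {
        "x_train": x[:n_train], "y_train": y[:n_train],
        "x_val": x[n_train:n_val], "y_val": y[n_train:n_val],
        "x_test": x[n_val:], "y_test": y[n_val:],
    }


@pytest.fixture(scope="session")
def trained_patch_model(patch_dataset):
    """Reduced-width (0.25) patch classifier trained 10 epochs on synthetic data."""
    d = patch_dataset
    hp = HyperParams(max_epochs=10, seed=0)
    net, history = train_model(
        build_proposed_cnn(0.25), d["x_train"], d["y_train"], d["x_val"], d["y_val"], hp
    )
    return net, history
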
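"""Network builders, parameter counting, gradients, training and metrics."""

import numpy as np
import pytest

from capclean.nn import (
    Activation,
    BatchNorm,
    Conv2D,
    Dense,
    Flatten,
    HyperParams,
    ModelSpec,
    Network,
    build_proposed_cnn,
    build_vgg16_classifier,
    count_parameters,
    evaluate,
    metrics_from_confusion,
    train_model,
    train_vgg_two_stage,
)


class TestParameterCounting:
    def test_single_conv_with_bias(self):
        spec = ModelSpec((Conv2D(3, 3, 32),), input_shape=(64, 64, 3))
        assert count_parameters(spec) == 9 * 3 * 32 + 32 == 896

    def test_batch_norm_counts_moving_statistics(self):
        spec = ModelSpec(
            (Conv2D(3, 3, 128), BatchNorm(128)), input_shape=(8, 8, 3)
        )
        assert count_parameters(spec) - (9 * 3 * 128 + 128) == 4 * 128 == 512

    def test_head_closed_form(self):
        for flat in (2048, 5120):
            spec = ModelSpec(
                (
                    Dense(flat, 128),
                    Activation("leaky_relu"),
                    BatchNorm(128),
                    Dense(128, 2),
                    Activation("softmax"),
                ),
                input_shape=(flat,),
            )
            assert count_parameters(spec) == flat * 128 + 128 + 512 + 258

    def test_vgg16_base_standard_count(self):
        spec = build_vgg16_classifier()
        head_start = next(
            i for i, l in enumerate(spec.layers) if isinstance(l, Flatten)
        )
        base = sum(l.n_parameters for l in spec.layers[:head_start])
        assert base == 14_714_688
        head = sum(l.n_parameters for l in spec.layers[head_start:])
        assert head == 2048 * 128 + 128 + 512 + 258 == 263_042

    def test_instantiated_network_matches_symbolic_count(self):
        for spec in (build_proposed_cnn(0.25), build_proposed_cnn(1.0)):
            assert Network(spec, seed=0).n_parameters == count_parameters(spec)

    def test_inconsistent_shapes_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec((Conv2D(3, 4, 8),), input_shape=(64, 64, 3))
        with pytest.raises(ValueError):
            ModelSpec((Flatten(), Dense(100, 2)), input_shape=(8, 8, 3))


class TestArchitectures:
    def test_proposed_has_four_stride2_layers_ending_at_4x4(self):
        spec = build_proposed_cnn()
        strided = [l for l in spec.layers if isinstance(l, Conv2D) and l.stride == 2]
        assert len(strided) == 4
        shapes = spec.infer_shapes()
        last_spatial = [s for s in shapes if len(s) == 3][-1]
        assert last_spatial[:2] == (4, 4)

    def test_proposed_has_no_pooling(self):
        from capclean.nn import MaxPool2D

        assert not any(isinstance(l, MaxPool2D) for l in build_proposed_cnn().layers)

    def test_width_multiplier_scales_channels(self):
        half = build_proposed_cnn(0.5)
        convs = [l for l in half.layers if isinstance(l, Conv2D)]
        assert convs[0].out_channels == 24 and convs[-1].out_channels == 160

    def test_softmax_outputs_sum_to_one(self, rng):
        net = Network(build_proposed_cnn(0.1), seed=0)
        x = rng.standard_normal((5, 64, 64, 3)).astype(np.float32)
        probs = net.forward(x)
        assert probs.shape == (5, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            build_proposed_cnn(0.0)


def _loss_and_probs(net, x, y_onehot):
    logits = net.forward_logits(x, training=True)
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return -(y_onehot * logp).sum() / len(x), np.exp(logp)


class TestGradients:
    @pytest.mark.parametrize("with_bn", [False, True])
    def test_backward_matches_numerical_gradient(self, rng, with_bn):
        layers = [Conv2D(3, 3, 4, stride=2), Activation("leaky_relu")]
        if with_bn:
            layers.append(BatchNorm(4))
        layers += [
            Conv2D(3, 4, 5, stride=2),
            Activation("leaky_relu"),
            Flatten(),
            Dense(2 * 2 * 5, 2),
            Activation("softmax"),
        ]
        net = Network(ModelSpec(tuple(layers), input_shape=(8, 8, 3)), seed=0)
        x = rng.standard_normal((4, 8, 8, 3)).astype(np.float32)
        y = np.eye(2, dtype=np.float32)[rng.integers(0, 2, 4)]
        _, probs = _loss_and_probs(net, x, y)
        net.backward_from_logits((probs - y) / 4)
        worst = 0.0
        for layer in net.layers:
            for name in layer.trainable_names:
                p = layer.params[name].reshape(-1)
                g = layer.grads[name].reshape(-1)
                for k in rng.choice(p.size, min(4, p.size), replace=False):
                    eps = 1e-3
                    old = p[k]
                    p[k] = old + eps
                    lp, _ = _loss_and_probs(net, x, y)
                    p[k] = old - eps
                    lm, _ = _loss_and_probs(net, x, y)
                    p[k] = old
                    num = (lp - lm) / (2 * eps)
                    worst = max(worst, abs(num - g[k]) / max(abs(num) + abs(g[k]), 1e-5))
        assert worst < 0.03  # float32 arithmetic with central differences


class TestTraining:
    def test_separable_color_patches_reach_perfect_validation(self):
        red = np.zeros((40, 64, 64, 3), dtype=np.float32)
        red[..., 0] = 1.0
        green = np.zeros((40, 64, 64, 3), dtype=np.float32)
        green[..., 1] = 1.0
        x = np.concatenate([red, green])
        y = np.array([0] * 40 + [1] * 40)
        hp = HyperParams(max_epochs=3, seed=0)
        net, hist = train_model(build_proposed_cnn(0.1), x[::2], y[::2], x[1::2], y[1::2], hp)
        assert hist.best_val_accuracy == 1.0

    def test_history_bookkeeping_contract(self, rng):
        x = rng.random((30, 64, 64, 3)).astype(np.float32)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        hp = HyperParams(max_epochs=4, seed=1)
        _, hist = train_model(build_proposed_cnn(0.05), x, y, x[:8], y[:8], hp)
        assert len(hist.val_accuracy) <= hp.max_epochs
        assert hist.best_val_accuracy == max(hist.val_accuracy)

    def test_single_class_training_rejected(self, rng):
        x = rng.random((10, 64, 64, 3)).astype(np.float32)
        with pytest.raises(ValueError):
            train_model(build_proposed_cnn(0.05), x, np.zeros(10, int), x, np.zeros(10, int))

    def test_training_is_deterministic_for_fixed_seed(self, rng):
        x = rng.random((24, 64, 64, 3)).astype(np.float32)
        y = np.tile([0, 1], 12)
        hp = HyperParams(max_epochs=2, seed=42)
        net1, h1 = train_model(build_proposed_cnn(0.05), x, y, x[:8], y[:8], hp)
        net2, h2 = train_model(build_proposed_cnn(0.05), x, y, x[:8], y[:8], hp)
        assert h1.train_loss == h2.train_loss
        for w1, w2 in zip(net1.get_weights(), net2.get_weights()):
            for k in w1:
                np.testing.assert_array_equal(w1[k], w2[k])


class TestTwoStage:
    def _toy_data(self, rng, n=24):
        x = rng.random((n, 64, 64, 3)).astype(np.float32)
        y = np.tile([0, 1], n // 2)
        return x, y

    def test_stage1_leaves_base_bit_identical_stage2_changes_it(self, rng):
        x, y = self._toy_data(rng)
        net = Network(build_proposed_cnn(0.05), seed=3)
        before = net.get_weights()
        head_start = net.head_start
        hp = HyperParams(max_epochs=1, seed=0, optimizer="sgd")
        train_vgg_two_stage(net, x, y, x[:8], y[:8], hp, stage1_epochs=1)
        # run stage 1 alone to inspect the freeze contract
        net2 = Network(build_proposed_cnn(0.05), seed=3)
        from capclean.nn.training import _fit

        _fit(net2, x, y, x[:8], y[:8], hp, frozen_prefix=head_start)
        after1 = net2.get_weights()
        for i in range(head_start):
            for k in before[i]:
                np.testing.assert_array_equal(before[i][k], after1[i][k])
        # full two-stage training must change base parameters
        changed = any(
            not np.array_equal(before[i][k], w[k])
            for i, w in enumerate(net.get_weights()[:head_start])
            for k in w
        )
        assert changed

    def test_two_stage_always_uses_sgd(self, rng):
        x, y = self._toy_data(rng, 8)
        net = Network(build_proposed_cnn(0.05), seed=0)
        hp = HyperParams(max_epochs=1, seed=0, optimizer="nadam")
        # the procedure overrides the optimizer to SGD internally; it must not raise
        train_vgg_two_stage(net, x, y, x[:4], y[:4], hp, stage1_epochs=1)


class TestMetrics:
    def test_worked_confusion_example(self):
        m = metrics_from_confusion(tp=45, tn=40, fp=10, fn=5)
        assert m.accuracy == pytest.approx(85.0)
        assert m.sensitivity == pytest.approx(90.0)
        assert m.specificity == pytest.approx(80.0)
        assert m.mcc == pytest.approx(0.7035, abs=1e-4)

    def test_perfect_predictions(self):
        m = metrics_from_confusion(tp=10, tn=10, fp=0, fn=0)
        assert m.accuracy == 100.0 and m.mcc == 1.0

    def test_degenerate_denominator_flags_mcc_zero(self):
        m = metrics_from_confusion(tp=10, tn=0, fp=10, fn=0)
        assert m.mcc == 0.0 and not m.mcc_defined

    def test_matches_sklearn_on_random_labelings(self, rng):
        from sklearn.metrics import accuracy_score, matthews_corrcoef

        for _ in range(20):
            y = rng.integers(0, 2, 50)
            p = rng.integers(0, 2, 50)
            tp = int(((p == 1) & (y == 1)).sum())
            tn = int(((p == 0) & (y == 0)).sum())
            fp = int(((p == 1) & (y == 0)).sum())
            fn = int(((p == 0) & (y == 1)).sum())
            m = metrics_from_confusion(tp, tn, fp, fn)
            assert m.accuracy == pytest.approx(100 * accuracy_score(y, p))
            assert m.mcc == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)

    def test_evaluate_thresholds_dirty_probability(self, rng):
        class Stub:
            def predict_proba(self, x):
                p = x.mean(axis=(1, 2, 3))
                return np.column_stack([1 - p, p])

        x = np.concatenate(
            [np.full((5, 4, 4, 3), 0.1, np.float32), np.full((5, 4, 4, 3), 0.9, np.float32)]
        )
        y = np.array([0] * 5 + [1] * 5)
        m = evaluate(Stub(), x, y)
        assert m.accuracy == 100.0

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate(None, np.zeros((0, 4, 4, 3)), np.zeros(0))


class TestPersistence:
    def test_hyperparams_json_round_trip(self, tmp_path):
        hp = HyperParams(batch_size=8, max_epochs=5, seed=3)
        hp.save(tmp_path / "hp.json")
        assert HyperParams.load(tmp_path / "hp.json") == hp

    def test_save_load_round_trip(self, tmp_path, rng):
        net = Network(build_proposed_cnn(0.05), seed=1)
        x = rng.random((3, 64, 64, 3)).astype(np.float32)
        before = net.predict_proba(x)
        net.save(tmp_path / "model")
        net2 = Network(build_proposed_cnn(0.05), seed=99)
        net2.load(tmp_path / "model")
        np.testing.assert_array_equal(net2.predict_proba(x), before)
        assert (tmp_path / "model.json").exists()
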
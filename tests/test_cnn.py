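import numpy as np
import pytest

from aegdi.cnn import (
    CnnSpec,
    ConfigurationError,
    Dropout,
    TrainSpec,
    aggregate_cycles,
    build_cnn,
    build_tcnn,
    conv_shapes,
    count_parameters,
    load_model,
    orthogonal_init,
    predict,
    save_model,
    train,
)


def tiny_spec(**kw):
    defaults = dict(
        input_height=12, input_width=14, input_channels=1,
        conv_layers=((3, 3, 2), (3, 3, 3)), pool_positions=(1, 2),
        fc1_width=6, output_classes=3,
    )
    defaults.update(kw)
    return CnnSpec(**defaults)


class TestShapeAlgebra:
    def test_reference_stack_dimensions(self):
        model = build_cnn(CnnSpec.for_task(output_classes=744, input_channels=2))
        assert conv_shapes(model) == [(30, 62), (15, 31), (13, 29), (11, 27), (5, 13)]

    def test_single_conv_removes_second_pool(self):
        model = build_cnn(
            CnnSpec.for_task(output_classes=10, input_channels=2, n_conv=1)
        )
        assert conv_shapes(model) == [(30, 62), (15, 31)]

    def test_all_nconv_variants_build(self):
        for n_conv in (1, 2, 3, 4):
            model = build_cnn(
                CnnSpec.for_task(
                    output_classes=5, input_channels=2,
                    feature_maps=(8, 8, 8, 8), n_conv=n_conv,
                )
            )
            assert all(h > 0 and w > 0 for h, w in conv_shapes(model))

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ConfigurationError, match="conv1"):
            build_cnn(tiny_spec(conv_layers=((15, 3, 2),), pool_positions=()))

    def test_eq_shape_recurrence(self):
        # every conv layer obeys M_l = M_{l-1} - P + 1 (no zero padding)
        model = build_cnn(tiny_spec())
        dims = [(12, 14)] + conv_shapes(model)
        # conv1: -2 both dims; pool: floor halve; conv2: -2; pool
        assert dims[1] == (dims[0][0] - 2, dims[0][1] - 2)
        assert dims[2] == (dims[1][0] // 2, dims[1][1] // 2)
        assert dims[3] == (dims[2][0] - 2, dims[2][1] - 2)


class TestParameterCount:
    def test_dense_1024_to_744(self):
        spec = CnnSpec(
            input_height=1, input_width=1, input_channels=1024,
            conv_layers=(), pool_positions=(), fc1_width=744, output_classes=2,
        )
        model = build_cnn(spec)
        fl1 = model.layers[-3]
        assert fl1.w.size + fl1.b.size == 1024 * 744 + 744 == 762_600

    def test_conv_3x3_2to32(self):
        spec = tiny_spec(conv_layers=((3, 3, 32),), pool_positions=(),
                         input_channels=2)
        model = build_cnn(spec)
        conv = model.layers[0]
        assert conv.w.size + conv.b.size == (3 * 3 * 2 + 1) * 32 == 608

    def test_counts_all_tensors(self):
        model = build_cnn(tiny_spec())
        assert count_parameters(model) == sum(p.size for p in model.params)


class TestForwardOracle:
    def test_hand_computed_convolution(self):
        # one 3x3 kernel on a 3x3 input: conv+bias+ReLU equals the direct sum
        spec = CnnSpec(input_height=3, input_width=3, input_channels=1,
                       conv_layers=((3, 3, 1),), pool_positions=(),
                       fc1_width=2, output_classes=2)
        model = build_cnn(spec, seed=0)
        conv = model.layers[0]
        x = np.arange(9, dtype=float).reshape(1, 1, 3, 3)
        conv.b[0] = 0.25
        expected = max(0.0, float((conv.w[0, 0] * x[0, 0]).sum()) + 0.25)
        out = conv.forward(x)
        assert out.shape == (1, 1, 1, 1)
        assert out[0, 0, 0, 0] == pytest.approx(expected, abs=1e-12)

    def test_gradients_match_finite_differences(self):
        model = build_cnn(tiny_spec(), seed=1)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 1, 12, 14))
        y = rng.integers(0, 3, 4)

        def loss():
            logits = model.forward(x, train=False)
            z = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
            return -np.mean(np.log(p[np.arange(4), y]))

        logits = model.forward(x, train=False)
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        model.backward((p - np.eye(3)[y]) / 4)
        grads = [g.copy() for g in model.grads]
        for param, grad in zip(model.params, grads):
            flat, gflat = param.ravel(), grad.ravel()
            for k in rng.choice(param.size, size=min(4, param.size), replace=False):
                eps, old = 1e-6, flat[k]
                flat[k] = old + eps
                lp = loss()
                flat[k] = old - eps
                lm = loss()
                flat[k] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(gflat[k], abs=1e-5, rel=1e-4)


class TestInitialisation:
    @pytest.mark.parametrize("shape", [(8, 20), (20, 8), (4, 2, 3, 3)])
    def test_orthogonality(self, shape):
        w = orthogonal_init(np.random.default_rng(0), shape)
        m = w.reshape(shape[0], -1)
        if m.shape[0] <= m.shape[1]:
            np.testing.assert_allclose(m @ m.T, np.eye(m.shape[0]), atol=1e-5)
        else:
            np.testing.assert_allclose(m.T @ m, np.eye(m.shape[1]), atol=1e-5)


class TestTraining:
    def _toy(self):
        rng = np.random.default_rng(0)
        a = np.full((1, 12, 14), 0.8)
        b = np.full((1, 12, 14), 2.2)
        imgs = np.stack([a] * 15 + [b] * 15) + rng.normal(0, 0.02, (30, 1, 12, 14))
        return imgs, np.array([0] * 15 + [1] * 15)

    def test_separable_toy_reaches_full_accuracy(self):
        imgs, labels = self._toy()
        spec = tiny_spec(conv_layers=((3, 3, 4),), pool_positions=(1,),
                         fc1_width=16, output_classes=2)
        model = build_cnn(spec, seed=0)
        clf = train(model, imgs, labels,
                    TrainSpec(epochs=5, batch_size=2, learning_rate=0.01, seed=0))
        assert (clf.predict_label(imgs) == labels).mean() == 1.0

    def test_zero_epochs_leaves_weights(self):
        imgs, labels = self._toy()
        model = build_cnn(tiny_spec(output_classes=2), seed=3)
        before = [p.copy() for p in model.params]
        train(model, imgs, labels, TrainSpec(epochs=0, seed=0))
        for b, p in zip(before, model.params):
            np.testing.assert_array_equal(b, p)

    def test_same_seed_same_loss(self):
        imgs, labels = self._toy()
        hist = []
        for _ in range(2):
            model = build_cnn(tiny_spec(output_classes=2), seed=4)
            clf = train(model, imgs, labels, TrainSpec(epochs=3, batch_size=10, seed=9))
            hist.append(clf.history)
        assert hist[0] == hist[1]

    def test_missing_class_warns(self):
        imgs, _ = self._toy()
        model = build_cnn(tiny_spec(output_classes=3), seed=0)
        with pytest.warns(UserWarning, match="classes"):
            train(model, imgs, np.zeros(len(imgs), dtype=int),
                  TrainSpec(epochs=1, seed=0))

    def test_paper_training_defaults(self):
        spec = TrainSpec()
        assert (spec.epochs, spec.batch_size, spec.learning_rate, spec.dropout) == (
            50, 100, 0.001, 0.5,
        )


class TestPredict:
    def test_probabilities_normalised(self, rng):
        model = build_cnn(tiny_spec(), seed=0)
        p = predict(model, rng.normal(size=(7, 1, 12, 14)))
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_rows_identical(self, rng):
        model = build_cnn(tiny_spec(), seed=0)
        x = rng.normal(size=(1, 1, 12, 14))
        p = predict(model, np.concatenate([x, x]))
        np.testing.assert_array_equal(p[0], p[1])

    def test_dimension_mismatch(self, rng):
        model = build_cnn(tiny_spec(), seed=0)
        with pytest.raises(ValueError, match="shape"):
            predict(model, rng.normal(size=(2, 1, 10, 10)))

    def test_untrained_model_reproducible(self, rng):
        x = rng.normal(size=(3, 1, 12, 14))
        p1 = predict(build_cnn(tiny_spec(), seed=8), x)
        p2 = predict(build_cnn(tiny_spec(), seed=8), x)
        np.testing.assert_array_equal(p1, p2)

    def test_dropout_only_in_training(self, rng):
        model = build_cnn(tiny_spec(), seed=0)
        x = rng.normal(size=(2, 1, 12, 14))
        gen = np.random.default_rng(0)
        out_train = model.forward(x, train=True, rng=gen)
        out_infer = model.forward(x, train=False)
        assert np.abs(out_train - out_infer).max() > 0
        for layer in model.layers:
            if isinstance(layer, Dropout):
                layer.p = 0.0
        out_p0 = model.forward(x, train=True, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out_p0, out_infer)


class TestAggregation:
    def test_single_vector(self):
        assert aggregate_cycles([[0.2, 0.8]]) == 1

    def test_unanimous(self):
        assert aggregate_cycles([[0.9, 0.1]] * 5) == 0

    def test_mean_probability_decides(self):
        assert aggregate_cycles([[0.6, 0.4], [0.1, 0.9]]) == 1

    def test_tie_takes_lowest_index(self):
        assert aggregate_cycles([[0.5, 0.5]]) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cycles([])

    def test_majority_vote_mode(self):
        probs = [[0.55, 0.45], [0.52, 0.48], [0.05, 0.95]]
        assert aggregate_cycles(probs, method="vote") == 0
        assert aggregate_cycles(probs, method="mean") == 1


class TestTcnn:
    def test_height_preserved(self):
        model = build_tcnn(CnnSpec.for_task(output_classes=744, input_channels=2))
        assert conv_shapes(model) == [(32, 62), (32, 31), (32, 29), (32, 27), (32, 13)]

    def test_parameter_count_differs_from_square(self):
        spec = CnnSpec.for_task(output_classes=10, input_channels=2,
                                feature_maps=(8, 8, 8), fc1_width=32)
        assert count_parameters(build_tcnn(spec)) != count_parameters(build_cnn(spec))


class TestPersistence:
    def test_round_trip_predictions(self, tmp_path, rng):
        imgs = rng.normal(size=(10, 1, 12, 14))
        labels = rng.integers(0, 2, 10)
        model = build_cnn(tiny_spec(output_classes=2), seed=0)
        clf = train(model, imgs, labels, TrainSpec(epochs=2, batch_size=5, seed=0))
        save_model(tmp_path / "m", clf)
        back = load_model(tmp_path / "m")
        np.testing.assert_allclose(
            back.predict_proba(imgs), clf.predict_proba(imgs), atol=1e-12
        )
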
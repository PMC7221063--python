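"""DBN regressor: CD-1 mechanics, gradients, training behavior, serialization."""

import numpy as np
import pytest

from emgforce import (
    DBNConfig,
    DBNModel,
    DivergenceError,
    RBMLayer,
    cd1_update,
    finetune,
    load_model,
    predict,
    pretrain,
    save_model,
    train_dbn,
)
from emgforce.dbn import hidden_size_for_inputs, loss_and_gradients


class TestCD1:
    def test_zero_parameters_give_half_probabilities(self):
        layer = RBMLayer(
            weights=np.zeros((3, 4)), visible_bias=np.zeros(3), hidden_bias=np.zeros(4)
        )
        probs = layer.hidden_probabilities(np.random.default_rng(0).standard_normal((5, 3)))
        np.testing.assert_allclose(probs, 0.5)

    def test_zero_learning_rate_is_noop(self):
        rng = np.random.default_rng(1)
        layer = RBMLayer.initialize(3, 4, rng)
        w0 = layer.weights.copy()
        cd1_update(layer, rng.standard_normal((8, 3)), rng, lr=0.0, momentum=0.0)
        np.testing.assert_array_equal(layer.weights, w0)

    def test_reconstruction_error_decreases_with_training(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((100, 2)) @ np.array([[1.0, 0.9], [0.9, 1.0]])
        data = (data - data.mean(0)) / data.std(0)
        layer = RBMLayer.initialize(2, 6, rng)
        first = None
        for epoch in range(200):
            _, err = cd1_update(layer, data, rng, lr=0.01, momentum=0.5)
            if first is None:
                first = err
        assert err < first

    def test_divergence_raises(self):
        rng = np.random.default_rng(3)
        layer = RBMLayer.initialize(2, 4, rng)
        with pytest.raises(DivergenceError):
            for _ in range(200):
                cd1_update(layer, 10.0 * rng.standard_normal((16, 2)), rng, lr=1e6)


class TestPretrain:
    def test_zero_epochs_leaves_initialization(self):
        X = np.random.default_rng(0).standard_normal((50, 2))
        model = DBNModel.initialize((2, 5, 5, 1), seed=4)
        w0 = model.rbm_stack[0].weights.copy()
        pretrain(model, X, DBNConfig(pretrain_epochs=0))
        np.testing.assert_array_equal(model.rbm_stack[0].weights, w0)
        assert not model.pretrained

    def test_determinism(self):
        X = np.random.default_rng(1).standard_normal((60, 3))
        runs = []
        for _ in range(2):
            model = DBNModel.initialize((3, 6, 6, 1), seed=9)
            pretrain(model, X, DBNConfig(pretrain_epochs=5))
            runs.append(model.rbm_stack[1].weights.copy())
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_feature_count_checked(self):
        model = DBNModel.initialize((3, 5, 5, 1), seed=0)
        with pytest.raises(ValueError):
            pretrain(model, np.zeros((10, 2)))


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        """Backprop gradients on a 4-5-5-1 net vs central differences, all
        parameters, max relative error < 1e-4."""
        rng = np.random.default_rng(5)
        model = DBNModel.initialize((4, 5, 5, 1), seed=5)
        # non-degenerate weights so no gradient is vanishingly small
        model.rbm_stack[0].weights = 0.8 * rng.standard_normal((4, 5))
        model.rbm_stack[1].weights = 0.8 * rng.standard_normal((5, 5))
        model.output_weights = 0.8 * rng.standard_normal(5)
        model.output_bias = 0.1
        model.set_standardization(rng.standard_normal((10, 4)))
        X = rng.standard_normal((3, 4))
        y = rng.uniform(0, 1, 3)
        _, grads = loss_and_gradients(model, X, y)
        eps = 1e-6
        worst = 0.0
        params = model._params()
        for name, arr in params.items():
            if np.isscalar(arr) or arr.ndim == 0 or name == "b3":
                model.output_bias += eps
                lp, _ = loss_and_gradients(model, X, y)
                model.output_bias -= 2 * eps
                lm, _ = loss_and_gradients(model, X, y)
                model.output_bias += eps
                fd = (lp - lm) / (2 * eps)
                rel = abs(fd - grads["b3"]) / max(abs(fd), 1e-8)
                worst = max(worst, rel)
                continue
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = loss_and_gradients(model, X, y)
                arr[idx] = orig - eps
                lm, _ = loss_and_gradients(model, X, y)
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                g = grads[name][idx]
                rel = abs(fd - g) / max(abs(fd), abs(g), 1e-8)
                worst = max(worst, rel)
        assert worst < 1e-4


class TestFinetune:
    def test_constant_target_learned(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((400, 2))
        y = np.full(400, 0.5)
        model = train_dbn(
            X, y, X[:50], y[:50], layer_sizes=(2, 8, 8, 1),
            config=DBNConfig(pretrain_epochs=2, finetune_epochs=100, patience=30), seed=6,
        )
        np.testing.assert_allclose(predict(model, X), 0.5, atol=0.01)

    def test_empty_validation_rejected(self):
        model = DBNModel.initialize((1, 4, 4, 1), seed=0)
        with pytest.raises(ValueError, match="validation"):
            finetune(model, np.zeros((10, 1)), np.zeros(10), np.zeros((0, 1)), np.zeros(0))

    def test_early_stopping_returns_best_snapshot(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, (300, 1))
        y = X.ravel() ** 2
        Xv = rng.uniform(0, 1, (80, 1))
        yv = Xv.ravel() ** 2
        model = train_dbn(
            X, y, Xv, yv, layer_sizes=(1, 10, 10, 1),
            config=DBNConfig(pretrain_epochs=2, finetune_epochs=60, patience=5), seed=7,
        )
        val_curve = model.training_log["finetune_val_mse"]
        returned = float(np.mean((predict(model, Xv) - yv) ** 2))
        assert returned == pytest.approx(min(val_curve), rel=1e-9)
        assert returned <= val_curve[-1] + 1e-15

    def test_full_training_reproducible(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, (200, 1))
        y = X.ravel() ** 2
        cfg = DBNConfig(pretrain_epochs=3, finetune_epochs=20, patience=10)
        m1 = train_dbn(X, y, X[:40], y[:40], layer_sizes=(1, 8, 8, 1), config=cfg, seed=11)
        m2 = train_dbn(X, y, X[:40], y[:40], layer_sizes=(1, 8, 8, 1), config=cfg, seed=11)
        np.testing.assert_array_equal(m1.output_weights, m2.output_weights)
        np.testing.assert_array_equal(m1.rbm_stack[0].weights, m2.rbm_stack[0].weights)

    def test_pretraining_does_not_hurt(self):
        """Pretrained-then-finetuned validation error <= random-init-then-
        finetuned, median over 10 seeds, on a small smooth task."""
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 1, (400, 1))
        y = np.sin(2.5 * X.ravel())
        Xv = rng.uniform(0, 1, (100, 1))
        yv = np.sin(2.5 * Xv.ravel())
        cfg_short = DBNConfig(pretrain_epochs=5, finetune_epochs=15, patience=15)
        diffs = []
        for seed in range(10):
            with_pre = train_dbn(X, y, Xv, yv, layer_sizes=(1, 10, 10, 1), config=cfg_short, seed=seed)
            no_pre = DBNModel.initialize((1, 10, 10, 1), seed=seed)
            no_pre.set_standardization(X)
            finetune(no_pre, X, y, Xv, yv, DBNConfig(pretrain_epochs=0, finetune_epochs=15, patience=15))
            diffs.append(
                no_pre.training_log["best_val_mse"] - with_pre.training_log["best_val_mse"]
            )
        assert np.median(diffs) >= 0.0


class TestPredict:
    def test_duplicate_rows_identical_outputs(self):
        model = DBNModel.initialize((2, 5, 5, 1), seed=0)
        model.set_standardization(np.random.default_rng(0).standard_normal((10, 2)))
        x = np.array([[0.3, 0.7], [0.3, 0.7]])
        out = predict(model, x)
        assert out[0] == out[1]

    def test_zero_weight_model_outputs_bias(self):
        model = DBNModel.initialize((2, 4, 4, 1), seed=0)
        model.rbm_stack[0].weights[:] = 0
        model.rbm_stack[1].weights[:] = 0
        model.output_weights[:] = 0
        model.output_bias = 0.37
        np.testing.assert_allclose(predict(model, np.ones((3, 2))), 0.37)

    def test_shape_mismatch_rejected(self):
        model = DBNModel.initialize((3, 4, 4, 1), seed=0)
        with pytest.raises(ValueError):
            predict(model, np.ones((5, 2)))

    def test_architecture_selection(self):
        assert hidden_size_for_inputs(1) == 80
        assert hidden_size_for_inputs(4) == 100


class TestSerialization:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(10)
        X = rng.uniform(0, 1, (150, 2))
        y = X.sum(axis=1) / 2
        model = train_dbn(
            X, y, X[:30], y[:30], layer_sizes=(2, 6, 6, 1),
            config=DBNConfig(pretrain_epochs=2, finetune_epochs=10, patience=5), seed=3,
        )
        path = tmp_path / "model.h5"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(predict(back, X), predict(model, X))
        assert back.layer_sizes == model.layer_sizes
        assert back.finetuned
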
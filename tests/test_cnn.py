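import copy

import numpy as np
import pytest

from nirecnn import (CNNConfig, build_submodel, leaky_relu, predict_submodel,
                     sigmoid, train_submodel)
from nirecnn.cnn import _forward
from nirecnn.dataset import TargetScaler
from nirecnn.nnet import Standardizer


class TestLeakyRelu:
    @pytest.mark.parametrize("x,a,expected", [
        (5.0, 10.0, 5.0),
        (-10.0, 10.0, -1.0),
        (0.0, 10.0, 0.0),
        (-3.0, 2.0, -1.5),
    ])
    def test_divisor_parameterization(self, x, a, expected):
        assert leaky_relu(x, a) == pytest.approx(expected)

    def test_divisor_must_exceed_one(self):
        with pytest.raises(ValueError):
            leaky_relu(1.0, 1.0)


class TestConfigValidation:
    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            CNNConfig(kernel_size=4)

    def test_stride_gt_one_rejected(self):
        with pytest.raises(ValueError):
            CNNConfig(stride=2)

    def test_padding_required(self):
        with pytest.raises(ValueError):
            CNNConfig(padding=False)


class TestArchitecture:
    def test_feature_map_and_output_layer_shapes(self):
        model = build_submodel(30, CNNConfig(seed=0))
        assert model.params["out_w"].size == 16 * 30
        assert model.params["out_b"].size == 1
        for l, W in enumerate(model.params["conv_W"]):
            c_in = 1 if l == 0 else 16
            assert W.shape == (16, c_in, 5)

    def test_single_layer_narrow_net(self):
        model = build_submodel(30, CNNConfig(n_conv_layers=1, n_filters=8,
                                             seed=0))
        assert model.params["out_w"].size == 8 * 30
        assert model.params["conv_W"][0].shape == (8, 1, 5)

    def test_conv_parameter_count_independent_of_nw(self):
        cfg = CNNConfig(seed=0)
        a = build_submodel(20, cfg)
        b = build_submodel(60, cfg, wavelength_indices=np.arange(60))
        conv_a = sum(W.size for W in a.params["conv_W"])
        conv_b = sum(W.size for W in b.params["conv_W"])
        assert conv_a == conv_b
        assert b.params["out_w"].size == 3 * a.params["out_w"].size

    def test_nw_below_kernel_rejected(self):
        with pytest.raises(ValueError):
            build_submodel(3, CNNConfig(seed=0))

    def test_zero_output_layer_predicts_midpoint(self):
        model = build_submodel(10, CNNConfig(seed=1))
        model.params["out_w"][:] = 0.0
        model.params["out_b"][:] = 0.0
        model.x_standardizer = Standardizer(np.ones((3, 10)))
        model.target_scaler = TargetScaler(0.0, 20.0)
        pred = predict_submodel(model, np.random.default_rng(0).normal(
            size=(5, 10)))
        # sigmoid(0) = 0.5 -> unscale(0.5) with [0,20]->[0.1,0.9] gives 10
        np.testing.assert_allclose(pred, 10.0, atol=1e-6)


from tests_oracle_helpers import loop_forward_oracle as _loop_forward_oracle


class TestForwardPass:
    def test_matches_loop_oracle(self):
        """Vectorized forward pass equals a direct loop evaluation of the
        convolution, activation and output equations on random weights."""
        rng = np.random.default_rng(8)
        cfg = CNNConfig(n_conv_layers=3, n_filters=4, dtype="float64", seed=8)
        model = build_submodel(12, cfg)
        # perturb running stats away from init so the oracle exercises them
        model.bn_running = [(rng.normal(scale=0.1, size=m.shape),
                             1.0 + rng.uniform(0, 0.5, size=v.shape))
                            for m, v in model.bn_running]
        X = rng.normal(size=(20, 12))
        from nirecnn.cnn import forward_scaled
        got = forward_scaled(model, X)
        want = _loop_forward_oracle(model, X)
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_prediction_batch_invariant(self, fast_cnn_config):
        """Inference-mode batch-norm is frozen: a sample's prediction does
        not depend on what else is in the batch."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 15))
        y = rng.uniform(0, 10, 30)
        model = build_submodel(15, fast_cnn_config)
        train_submodel(model, X, y)
        full = predict_submodel(model, X)
        single = np.array([predict_submodel(model, X[i:i + 1])[0]
                           for i in range(5)])
        np.testing.assert_allclose(full[:5], single, rtol=1e-6)

    def test_duplicated_rows_get_identical_predictions(self, fast_cnn_config):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 15))
        y = rng.uniform(0, 10, 20)
        model = build_submodel(15, fast_cnn_config)
        train_submodel(model, X, y)
        X2 = np.vstack([X[0], X[0], X[1]])
        pred = predict_submodel(model, X2)
        assert pred[0] == pred[1]

    def test_prediction_independent_of_memory_layout(self, fast_cnn_config):
        """Full-grid inputs sliced internally must match pre-sliced inputs
        regardless of the array's memory order."""
        rng = np.random.default_rng(5)
        full = rng.normal(size=(10, 40))
        idx = np.sort(rng.choice(40, 15, replace=False))
        model = build_submodel(15, fast_cnn_config, wavelength_indices=idx)
        train_submodel(model, np.ascontiguousarray(full[:, idx]),
                       rng.uniform(0, 10, 10))
        a = predict_submodel(model, full)                  # sliced internally
        b = predict_submodel(model, np.ascontiguousarray(full[:, idx]))
        c = predict_submodel(model, np.asfortranarray(full)[:, idx])
        np.testing.assert_allclose(a, b, rtol=1e-10)
        np.testing.assert_allclose(a, c, rtol=1e-10)


class TestTraining:
    def test_loss_decreases(self, fast_cnn_config):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 15))
        y = X[:, 3] * 2 + 5 + 0.1 * rng.normal(size=25)
        model = build_submodel(15, fast_cnn_config)
        train_submodel(model, X, np.clip(y, 0, None))
        assert model.loss_trajectory[-1] < model.loss_trajectory[0]

    def test_seeded_determinism(self, fast_cnn_config):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 15))
        y = rng.uniform(0, 10, 20)
        m1 = build_submodel(15, fast_cnn_config)
        m2 = build_submodel(15, fast_cnn_config)
        train_submodel(m1, X, y)
        train_submodel(m2, X, y)
        np.testing.assert_array_equal(m1.params["out_w"], m2.params["out_w"])
        np.testing.assert_array_equal(m1.params["conv_W"][0],
                                      m2.params["conv_W"][0])

    def test_noiseless_linear_relation_is_learned(self):
        """A clean affine concentration signal across 25 channels is fit to
        high accuracy within the default training budget."""
        rng = np.random.default_rng(9)
        c = rng.uniform(0, 10, 60)
        profile = rng.normal(size=25)
        X = np.outer(c, profile) + 0.01 * rng.normal(size=(60, 25))
        model = build_submodel(25, CNNConfig(n_iterations=2000, seed=9))
        train_submodel(model, X, c)
        pred = predict_submodel(model, X)
        ss_res = np.sum((pred - c) ** 2)
        ss_tot = np.sum((c - c.mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.99

    def test_untrained_model_cannot_predict(self):
        model = build_submodel(10, CNNConfig(seed=0))
        with pytest.raises(RuntimeError):
            predict_submodel(model, np.zeros((2, 10)))

    def test_column_mismatch_rejected(self, fast_cnn_config):
        model = build_submodel(15, fast_cnn_config,
                               wavelength_indices=np.arange(30, 45))
        rng = np.random.default_rng(0)
        train_submodel(model, rng.normal(size=(10, 15)),
                       rng.uniform(0, 5, 10))
        with pytest.raises(ValueError):
            predict_submodel(model, np.zeros((2, 20)))


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Backward pass checked against central finite differences in
        float64 on a tiny network."""
        from nirecnn.cnn import _conv_same_backward

        rng = np.random.default_rng(13)
        N, nw = 5, 9
        cfg = CNNConfig(n_conv_layers=2, n_filters=3, dtype="float64", seed=5)
        base = build_submodel(nw, cfg)
        x = rng.normal(size=(N, nw, 1))
        yt = rng.uniform(0.2, 0.8, N)

        def loss_of(model):
            mm = copy.deepcopy(model)
            pred, _ = _forward(mm, x, training=True)
            return np.mean((pred - yt) ** 2)

        model = copy.deepcopy(base)
        p = model.params
        pred, (cache, flat, hshape) = _forward(model, x, training=True)
        resid = pred - yt
        dlogit = (2.0 / N) * resid * pred * (1.0 - pred)
        d_out_w = flat.T @ dlogit
        dh = np.outer(dlogit, p["out_w"]).reshape(hshape)
        grads = {"out_w": d_out_w}
        for l in reversed(range(cfg.n_conv_layers)):
            xhat, inv_std, cols, gmask = cache[l]
            dz = dh * gmask
            dbn, dW, db = _conv_same_backward(dz, cols, p["conv_W"][l])
            gamma = p["bn_gamma"][l]
            C = dbn.shape[2]
            dg = (dbn * xhat).reshape(-1, C).sum(0)
            dbeta = dbn.reshape(-1, C).sum(0)
            M = dbn.shape[0] * dbn.shape[1]
            dh = (inv_std / M) * (M * dbn * gamma - gamma * dbeta
                                  - xhat * (gamma * dg))
            grads[f"conv_W{l}"] = dW
            grads[f"bn_gamma{l}"] = dg

        eps = 1e-6
        arrays = {"out_w": base.params["out_w"],
                  "conv_W0": base.params["conv_W"][0],
                  "conv_W1": base.params["conv_W"][1],
                  "bn_gamma1": base.params["bn_gamma"][1]}
        for name, arr in arrays.items():
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = arr[i]
                arr[i] = orig + eps
                lp = loss_of(base)
                arr[i] = orig - eps
                lm = loss_of(base)
                arr[i] = orig
                num[i] = (lp - lm) / (2 * eps)
            scale = max(np.abs(num).max(), 1e-10)
            assert np.abs(num - grads[name]).max() / scale < 1e-6, name
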
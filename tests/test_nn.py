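"""Layer primitives: activation identities, oracle agreement, gradients.

Every backward pass is checked against central finite differences in
float64; forward passes are checked against the loop-based reference
implementations (`seizurecae.nn.reference`).
"""

import numpy as np
import pytest

from seizurecae.nn import reference as ref
from seizurecae.nn.functional import relu, sigmoid
from seizurecae.nn.layers import (BatchNorm, Conv2D, CropTo, Dense, Flatten,
                                  MaxPool2D, ReLU, Sigmoid, SqueezeAxis,
                                  Upsample2D)
from seizurecae.nn.optim import Adam, make_optimizer
from seizurecae.nn.recurrent import BiLSTM, LSTM, LSTMCellParams, lstm_step

rng = np.random.default_rng(1234)


def finite_diff_input(layer, x, R, eps=1e-6):
    layer.forward(x.copy())
    dx = layer.backward(R.copy()).copy()
    num = np.zeros_like(x)
    for k in range(x.size):
        old = x.flat[k]
        x.flat[k] = old + eps
        fp = float((layer.forward(x.copy()) * R).sum())
        x.flat[k] = old - eps
        fm = float((layer.forward(x.copy()) * R).sum())
        x.flat[k] = old
        num.flat[k] = (fp - fm) / (2 * eps)
    return dx, num


def finite_diff_params(layer, x, R, eps=1e-6):
    layer.forward(x.copy())
    layer.backward(R.copy())
    grads = {k: v.copy() for k, v in layer.grads.items()}
    out = {}
    for name, p in layer.params.items():
        num = np.zeros_like(p, dtype=float)
        for k in range(p.size):
            old = p.flat[k]
            p.flat[k] = old + eps
            fp = float((layer.forward(x.copy()) * R).sum())
            p.flat[k] = old - eps
            fm = float((layer.forward(x.copy()) * R).sum())
            p.flat[k] = old
            num.flat[k] = (fp - fm) / (2 * eps)
        out[name] = (grads[name], num)
    return out


class TestActivations:
    def test_relu_values(self):
        assert relu(-3.0) == 0.0
        assert relu(2.0) == 2.0
        assert relu(0.0) == 0.0

    def test_sigmoid_closed_form(self):
        assert sigmoid(0.0) == pytest.approx(0.5)
        assert sigmoid(np.log(3.0)) == pytest.approx(0.75, abs=1e-12)

    def test_sigmoid_symmetry_and_overflow_safety(self):
        ys = np.linspace(-1e4, 1e4, 101)
        out = sigmoid(ys)
        assert np.isfinite(out).all()
        assert (out > 0).all() and (out < 1).all() or \
            np.allclose(out[0], 0) and np.allclose(out[-1], 1)
        np.testing.assert_allclose(sigmoid(-ys), 1 - sigmoid(ys), atol=1e-12)


class TestForwardOracles:
    @pytest.mark.parametrize("cout", [1, 3, 8])
    def test_conv_matches_sliding_window(self, cout):
        x = rng.standard_normal((2, 6, 5, 3))
        conv = Conv2D(3, cout, rng=rng)
        got = conv.forward(x)
        want = ref.conv2d_reference(x, conv.params["W"], conv.params["b"])
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_conv_identity_kernel(self):
        conv = Conv2D(1, 1, kernel=(1, 1), rng=rng)
        conv.params["W"][:] = 1.0
        x = rng.standard_normal((2, 5, 4, 1))
        np.testing.assert_allclose(conv.forward(x), x)

    def test_conv_all_ones_kernel_interior_value(self):
        conv = Conv2D(1, 1, rng=rng)
        conv.params["W"][:] = 1.0
        x = np.ones((1, 6, 6, 1))
        y = conv.forward(x)
        assert y[0, 3, 2, 0] == pytest.approx(6.0)  # 3x2 window of ones

    def test_conv_feature_map_count(self):
        conv = Conv2D(1, 32, rng=rng)
        assert conv.forward(np.zeros((1, 8, 5, 1))).shape[-1] == 32

    @pytest.mark.parametrize("shape", [(2, 7, 7, 3), (1, 8, 6, 2),
                                       (3, 5, 23, 1)])
    @pytest.mark.parametrize("window", [(2, 2), (2, 3)])
    def test_pool_matches_window_enumeration(self, shape, window):
        x = rng.standard_normal(shape)
        got = MaxPool2D(window).forward(x)
        np.testing.assert_array_equal(got, ref.max_pool_reference(x, window))

    def test_channel_axis_pooling_trace(self):
        """23 channels survive the (2,2),(2,2),(2,2),(2,3) pool plan."""
        widths = [23]
        for win in [(2, 2), (2, 2), (2, 2), (2, 3)]:
            widths.append(-(-widths[-1] // win[1]))
        assert widths == [23, 12, 6, 3, 1]

    def test_upsample_repetition_and_inverse(self):
        x = rng.standard_normal((2, 4, 3, 2))
        up = Upsample2D((2, 3))
        y = up.forward(x)
        np.testing.assert_array_equal(y, ref.upsample_reference(x, (2, 3)))
        assert y.shape == (2, 8, 9, 2)
        # pooling with the same factor undoes repetition exactly
        np.testing.assert_array_equal(MaxPool2D((2, 3)).forward(y), x)

    def test_batchnorm_defining_property(self):
        x = rng.standard_normal((8, 5, 4, 3)) * 2 + 1
        bn = BatchNorm(3)
        y = bn.forward(x, train=True)
        np.testing.assert_allclose(y.mean(axis=(0, 1, 2)), 0, atol=1e-7)
        np.testing.assert_allclose(y.reshape(-1, 3).std(axis=0), 1,
                                   atol=2e-3)  # eps shrinks the std slightly

    def test_batchnorm_affine_parameters(self):
        x = rng.standard_normal((64, 2))
        bn = BatchNorm(2, eps=1e-8)
        bn.params["gamma"][:] = 2.0
        bn.params["beta"][:] = 3.0
        y = bn.forward(x, train=True)
        np.testing.assert_allclose(y.mean(axis=0), 3.0, atol=1e-6)
        np.testing.assert_allclose(y.std(axis=0), 2.0, atol=1e-4)

    def test_batchnorm_constant_feature_collapses_to_beta(self):
        x = np.ones((6, 3))
        bn = BatchNorm(3)
        bn.params["beta"][:] = 0.7
        np.testing.assert_allclose(bn.forward(x, train=True), 0.7, atol=1e-9)

    def test_batchnorm_batch_of_one_rejected(self):
        with pytest.raises(ValueError):
            BatchNorm(2).forward(np.ones((1, 4, 4, 2)), train=True)

    def test_batchnorm_inference_uses_running_stats(self):
        bn = BatchNorm(2, momentum=0.0)  # running stats = last batch
        x = rng.standard_normal((128, 2)) * 3 + 5
        bn.forward(x, train=True)
        y = bn.forward(x, train=False)
        yt = bn.forward(x, train=True)
        np.testing.assert_allclose(y, yt, atol=1e-6)


class TestGradients:
    @pytest.mark.parametrize("make,shape", [
        (lambda: Conv2D(2, 5, rng=rng), (2, 6, 5, 2)),
        (lambda: Conv2D(3, 1, rng=rng), (2, 5, 4, 3)),
        (lambda: MaxPool2D((2, 2)), (2, 7, 7, 2)),
        (lambda: MaxPool2D((2, 3)), (2, 6, 7, 2)),
        (lambda: Upsample2D((2, 3)), (2, 3, 2, 2)),
        (lambda: BatchNorm(2), (3, 4, 5, 2)),
        (lambda: ReLU(), (3, 4, 2, 2)),
        (lambda: ReLU(inplace=True), (3, 4, 2, 2)),
        (lambda: Sigmoid(), (3, 4, 2, 2)),
        (lambda: Dense(6, 3, rng=rng), (5, 6)),
        (lambda: Flatten(), (3, 2, 2, 2)),
        (lambda: CropTo(3, 2), (2, 4, 3, 2)),
        (lambda: SqueezeAxis(2), (2, 4, 1, 3)),
    ])
    def test_backward_matches_finite_differences(self, make, shape):
        layer = make()
        x = rng.standard_normal(shape)
        R = rng.standard_normal(layer.forward(x.copy()).shape)
        dx, num = finite_diff_input(layer, x, R)
        np.testing.assert_allclose(dx, num, atol=5e-7)
        if layer.params:
            for name, (got, want) in finite_diff_params(layer, x, R).items():
                np.testing.assert_allclose(got, want, atol=5e-7,
                                           err_msg=name)


class TestLSTM:
    def make_params(self, in_features=3, units=2, scale=0.4, seed=0):
        r = np.random.default_rng(seed)
        w = lambda: scale * r.standard_normal((units + in_features, units))
        b = lambda: scale * r.standard_normal(units)
        return LSTMCellParams(X_j=w(), X_k=w(), X_l=w(), X_b=w(),
                              a_j=b(), a_k=b(), a_l=b(), a_b=b())

    def test_zero_weights_zero_fixed_point(self):
        units, feats = 3, 2
        z = np.zeros((units + feats, units))
        p = LSTMCellParams(z, z.copy(), z.copy(), z.copy(),
                           np.zeros(units), np.zeros(units),
                           np.zeros(units), np.zeros(units))
        h, b = lstm_step(p, np.zeros(feats), np.zeros(units), np.zeros(units))
        np.testing.assert_array_equal(h, 0)
        np.testing.assert_array_equal(b, 0)

    def test_saturated_forget_gate_carries_state(self):
        z = np.zeros((2, 1))
        p = LSTMCellParams(z, z.copy(), z.copy(), z.copy(),
                           a_j=np.array([20.0]), a_k=np.array([-20.0]),
                           a_l=np.array([0.0]), a_b=np.array([0.0]))
        _, b = lstm_step(p, np.zeros(1), np.zeros(1), np.ones(1))
        assert b[0] == pytest.approx(1.0, abs=1e-8)

    def test_sequence_matches_recurrence_oracle(self):
        params = self.make_params()
        seq = rng.standard_normal((4, 3))
        # drive the production layer with the same parameters
        lstm = LSTM(3, 2, rng=rng)
        W = np.concatenate([params.X_j, params.X_k, params.X_l, params.X_b],
                           axis=1)
        lstm.params["W"] = W
        lstm.params["b"] = np.concatenate([params.a_j, params.a_k,
                                           params.a_l, params.a_b])
        got = lstm.forward(seq[None])[0]
        want = ref.lstm_sequence_reference(params, seq)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        p = self.make_params()
        with pytest.raises(ValueError):
            lstm_step(p, np.zeros(5), np.zeros(2), np.zeros(2))

    def test_bilstm_zero_weights_zero_average(self):
        bi = BiLSTM(3, 2, rng=rng)
        for cell in bi.sublayers:
            cell.params["W"][:] = 0
            cell.params["b"][:] = 0
        out = bi.forward(rng.standard_normal((2, 5, 3)))
        np.testing.assert_array_equal(out, 0)

    def test_bilstm_single_step_equals_that_step(self):
        bi = BiLSTM(3, 2, rng=rng)
        x = rng.standard_normal((1, 1, 3))
        out = bi.forward(x)
        hf = bi.forward_cell.forward(x)[:, 0, :]
        hb = bi.backward_cell.forward(x)[:, 0, :]
        np.testing.assert_allclose(out,
                                   np.concatenate([hf, hb], axis=1))

    def test_bilstm_reversal_swaps_direction_halves(self):
        """With tied direction parameters, reversing the sequence swaps
        the forward/backward halves of the time-averaged output."""
        bi = BiLSTM(3, 2, rng=rng)
        for name in ("W", "b"):
            bi.backward_cell.params[name] = bi.forward_cell.params[
                name].copy()
        x = rng.standard_normal((2, 6, 3))
        out = bi.forward(x)
        out_rev = bi.forward(x[:, ::-1, :].copy())
        np.testing.assert_allclose(out_rev[:, :2], out[:, 2:], atol=1e-12)
        np.testing.assert_allclose(out_rev[:, 2:], out[:, :2], atol=1e-12)

    def test_bilstm_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            BiLSTM(3, 2, rng=rng).forward(np.zeros((2, 0, 3)))

    def test_bilstm_gradients(self):
        bi = BiLSTM(3, 2, rng=np.random.default_rng(9))
        x = rng.standard_normal((2, 4, 3))
        R = rng.standard_normal((2, 4))
        bi.forward(x.copy())
        dx = bi.backward(R.copy()).copy()
        eps = 1e-6
        num = np.zeros_like(x)
        for k in range(x.size):
            old = x.flat[k]
            x.flat[k] = old + eps
            fp = float((bi.forward(x.copy()) * R).sum())
            x.flat[k] = old - eps
            fm = float((bi.forward(x.copy()) * R).sum())
            x.flat[k] = old
            num.flat[k] = (fp - fm) / (2 * eps)
        np.testing.assert_allclose(dx, num, atol=5e-7)


class TestOptimizers:
    @pytest.mark.parametrize("name", ["adam", "sgd", "rmsprop", "adadelta"])
    def test_optimizer_decreases_quadratic(self, name):
        layer = Dense(3, 1, rng=np.random.default_rng(0))
        target = np.array([[1.0], [2.0], [3.0]])
        x = np.eye(3)
        opt = make_optimizer(name, learning_rate=0.05)

        def loss():
            return float(((layer.forward(x) - target) ** 2).mean())

        before = loss()
        for _ in range(50):
            out = layer.forward(x)
            layer.backward(2 * (out - target) / out.size)
            opt.step([layer])
        assert loss() < before

    def test_unknown_optimizer_rejected(self):
        with pytest.raises(ValueError):
            make_optimizer("adamw", 1e-3)

    def test_adam_bias_correction_first_step(self):
        layer = Dense(1, 1, rng=np.random.default_rng(0))
        layer.params["W"][:] = 1.0
        layer.grads = {"W": np.array([[0.5]]), "b": np.zeros(1)}
        Adam(learning_rate=0.1).step([layer])
        # first step moves by ~lr regardless of gradient magnitude
        assert layer.params["W"][0, 0] == pytest.approx(0.9, abs=1e-6)
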
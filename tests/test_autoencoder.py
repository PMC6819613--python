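"""Autoencoder cost, gradients, training, stacking and integration."""

import numpy as np
import pytest

from dfnforest.autoencoder import (
    AEParameters,
    AutoencoderError,
    TrainConfig,
    TrainingDivergedError,
    ae_loss,
    _ae_gradients,
    encode,
    integrate_representations,
    initialize_parameters,
    sae_encode,
    train_ae,
    train_sae,
)


def _identity_params(n):
    return AEParameters(
        W=np.eye(n), b_x=np.zeros(n), W_prime=np.eye(n), b_h=np.zeros(n)
    )


class TestLoss:
    def test_zero_loss_on_exact_reconstruction(self):
        # tanh(0) = 0 and the affine decoder reproduces it: loss is exactly 0
        params = _identity_params(3)
        X = np.zeros((4, 3))
        assert ae_loss(params, X, lambda_=0.0) == 0.0

    def test_regularizer_isolated(self):
        params = _identity_params(3)
        X = np.zeros((4, 3))
        assert ae_loss(params, X, lambda_=0.7) == pytest.approx(0.7 * 3.0)

    def test_matches_scalar_hand_computation(self):
        # 1 sample, 2 features, 1 hidden unit; every step done in scalars
        W = np.array([[0.3, -0.2]])
        b_x = np.array([0.1])
        W_prime = np.array([[0.5], [-0.4]])
        b_h = np.array([0.05, -0.03])
        x = np.array([0.7, 0.2])
        h = np.tanh(0.3 * 0.7 + (-0.2) * 0.2 + 0.1)
        x0 = 0.5 * h + 0.05
        x1 = -0.4 * h - 0.03
        expected = (0.7 - x0) ** 2 + (0.2 - x1) ** 2 + 0.01 * (0.3**2 + 0.2**2)
        params = AEParameters(W=W, b_x=b_x, W_prime=W_prime, b_h=b_h)
        assert ae_loss(params, x[None, :], lambda_=0.01) == pytest.approx(expected)

    def test_loss_decomposition_exact(self, rng):
        for _ in range(30):
            n, m = rng.integers(2, 6), rng.integers(1, 5)
            params = initialize_parameters(n, m, rng)
            X = rng.standard_normal((5, n))
            lam = float(rng.uniform(0.01, 2.0))
            assert ae_loss(params, X, lam) - ae_loss(params, X, 0.0) == pytest.approx(
                lam * np.sum(params.W**2), rel=1e-12
            )

    def test_shape_mismatch_raises(self):
        with pytest.raises(AutoencoderError, match="features"):
            ae_loss(_identity_params(3), np.zeros((2, 4)))


class TestGradients:
    @pytest.mark.parametrize("activation", ["tanh", "sigmoid"])
    def test_analytic_gradient_matches_finite_differences(self, rng, activation):
        n, m, N = 4, 3, 6
        params = initialize_parameters(n, m, rng)
        X = rng.standard_normal((N, n))
        lam = 0.05
        grads = _ae_gradients(params, X, lam, activation)
        eps = 1e-6
        for gi, name in enumerate(("W", "b_x", "W_prime", "b_h")):
            arr = getattr(params, name)
            numeric = np.zeros_like(arr)
            for idx in np.ndindex(arr.shape):
                orig = arr[idx]
                arr[idx] = orig + eps
                up = ae_loss(params, X, lam, activation)
                arr[idx] = orig - eps
                down = ae_loss(params, X, lam, activation)
                arr[idx] = orig
                numeric[idx] = (up - down) / (2 * eps)
            np.testing.assert_allclose(grads[gi], numeric, rtol=1e-5, atol=1e-7)


class TestEncode:
    def test_zero_weights_give_zero_code(self):
        params = AEParameters(
            W=np.zeros((2, 3)), b_x=np.zeros(2), W_prime=np.zeros((3, 2)), b_h=np.zeros(3)
        )
        np.testing.assert_array_equal(encode(params, np.ones((4, 3))), np.zeros((4, 2)))

    def test_matches_scalar_hand_computation(self):
        W = np.array([[0.5, -1.0], [0.25, 2.0]])
        params = AEParameters(
            W=W, b_x=np.array([0.1, -0.2]), W_prime=np.zeros((2, 2)), b_h=np.zeros(2)
        )
        x = np.array([0.4, 0.3])
        expected = [
            np.tanh(0.5 * 0.4 + (-1.0) * 0.3 + 0.1),
            np.tanh(0.25 * 0.4 + 2.0 * 0.3 - 0.2),
        ]
        np.testing.assert_allclose(encode(params, x[None, :])[0], expected)

    def test_code_width_is_hidden_dim(self, rng):
        params = initialize_parameters(7, 3, rng)
        assert encode(params, rng.standard_normal((5, 7))).shape == (5, 3)


class TestTraining:
    def test_low_rank_data_reaches_near_svd_floor(self, rng):
        # rank-1 data with amplitudes in the near-linear regime of tanh:
        # a converged 1-unit AE must approach exact reconstruction
        u = 0.4 * rng.standard_normal((40, 1))
        v = rng.standard_normal((1, 6))
        X = u @ v
        cfg = TrainConfig(epochs=2000, learning_rate=3e-2, lambda_=0.0, seed=1)
        params = train_ae(X, 1, cfg)
        assert params.loss_trace[-1] < 0.01 * params.initial_loss

    def test_single_epoch_trace_and_update(self, rng):
        X = rng.standard_normal((10, 4))
        params = train_ae(X, 2, TrainConfig(epochs=1, learning_rate=1e-3, seed=0))
        assert len(params.loss_trace) == 1

    def test_vanishing_learning_rate_returns_initialization(self, rng):
        X = rng.standard_normal((10, 4))
        cfg = TrainConfig(epochs=3, learning_rate=1e-15, seed=5)
        params = train_ae(X, 2, cfg)
        init = initialize_parameters(
            4, 2, np.random.default_rng(np.random.SeedSequence(5))
        )
        np.testing.assert_allclose(params.W, init.W, atol=1e-12)
        np.testing.assert_allclose(params.W_prime, init.W_prime, atol=1e-12)

    def test_full_batch_descent_trace_nonincreasing(self, rng):
        X = rng.standard_normal((15, 5))
        params = train_ae(X, 3, TrainConfig(epochs=50, learning_rate=1e-4, seed=2))
        trace = np.array([params.initial_loss] + params.loss_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_divergence_reports_epoch(self, rng):
        X = 100.0 * rng.standard_normal((10, 4))
        with pytest.raises(TrainingDivergedError, match="epoch"):
            train_ae(X, 2, TrainConfig(epochs=200, learning_rate=50.0, seed=0))

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((12, 5))
        cfg = TrainConfig(epochs=20, learning_rate=1e-3, seed=9)
        a = train_ae(X, 2, cfg)
        b = train_ae(X, 2, cfg)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.W_prime, b.W_prime)

    def test_invalid_config_rejected(self):
        with pytest.raises(AutoencoderError):
            TrainConfig(epochs=0)
        with pytest.raises(AutoencoderError):
            TrainConfig(learning_rate=0.0)


class TestStackingAndIntegration:
    def test_stack_code_widths(self, rng):
        X = rng.standard_normal((20, 30))
        cfg = TrainConfig(epochs=3, learning_rate=1e-3, seed=0)
        model = train_sae(X, [12, 5], cfg)
        assert model.dims == [12, 5]
        assert sae_encode(model, X).shape == (20, 5)
        assert model.layers[1].input_dim == 12

    def test_stack_on_low_rank_data_reconstructs(self, rng):
        u = 0.3 * rng.standard_normal((30, 2))
        X = u @ rng.standard_normal((2, 8))
        cfg = TrainConfig(epochs=2000, learning_rate=3e-2, seed=3)
        model = train_sae(X, [2], cfg)
        assert model.layers[0].loss_trace[-1] < 0.01 * model.layers[0].initial_loss

    def test_integration_concatenates_then_compresses(self, rng):
        codes = [rng.standard_normal((15, 5)) for _ in range(3)]
        cfg = TrainConfig(epochs=2, learning_rate=1e-3, seed=0)
        layer, Z = integrate_representations(codes, 5, cfg)
        assert layer.input_dim == 15
        assert Z.shape == (15, 5)

    def test_integration_sample_mismatch_raises(self, rng):
        codes = [rng.standard_normal((10, 4)), rng.standard_normal((9, 4))]
        with pytest.raises(AutoencoderError, match="sample count"):
            integrate_representations(codes, 3, TrainConfig(epochs=1))

    def test_sae_archive_round_trips_exactly(self, rng, tmp_path):
        from dfnforest.autoencoder import load_sae, save_sae

        X = rng.standard_normal((15, 9))
        model = train_sae(X, [5, 2], TrainConfig(epochs=4, seed=7))
        path = tmp_path / "sae.npz"
        save_sae(model, path)
        loaded = load_sae(path)
        assert loaded.dims == model.dims and loaded.activation == model.activation
        for a, b in zip(model.layers, loaded.layers):
            np.testing.assert_array_equal(a.W, b.W)
            np.testing.assert_array_equal(a.b_x, b.b_x)
            np.testing.assert_array_equal(a.W_prime, b.W_prime)
            np.testing.assert_array_equal(a.b_h, b.b_h)

    def test_single_block_integration_reconstructs(self, rng):
        # one block, integrator width == code width: near-lossless transform
        code = rng.standard_normal((40, 4))
        cfg = TrainConfig(epochs=1500, learning_rate=2e-2, lambda_=0.0, seed=1)
        layer, Z = integrate_representations([code], 4, cfg)
        from dfnforest.autoencoder import reconstruct

        resid = code - reconstruct(layer, code)
        assert np.mean(resid**2) < 0.05 * np.var(code)
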
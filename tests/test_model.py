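"""Unit tests for the restricted-latent VAE building blocks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resvae_ensemble import (
    ClusterAssignment,
    ExpressionMatrix,
    ModelConfig,
    mish,
    restrict_latent,
    smooth_labels,
    train_model,
    vae_loss,
)
from resvae_ensemble.model import _batch_forward_backward, _init_params, preprocess
from resvae_ensemble.nn import (
    glorot_uniform,
    he_uniform,
    init_for_activation,
    mish_grad,
    relu_grad,
)


class TestMish:
    @pytest.mark.parametrize(
        "x, expected, tol",
        [
            (0.0, 0.0, 0.0),
            (1.0, 0.8650984, 1e-6),
        ],
    )
    def test_values(self, x, expected, tol):
        assert mish(x) == pytest.approx(expected, abs=max(tol, 1e-12))

    def test_large_negative_asymptote(self):
        # mish(x) ~ x * e^x for x << 0: tiny but strictly negative
        v = mish(-40.0)
        assert -1e-10 < v < 0

    def test_stable_for_large_inputs(self):
        x = np.array([-50.0, 50.0])
        v = mish(x)
        assert np.all(np.isfinite(v))
        assert v[1] == pytest.approx(50.0, rel=1e-12)  # identity for large x

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            mish(np.array([1.0, np.nan]))

    def test_monotone_and_bounded_below(self):
        grid = np.linspace(-20, 20, 4001)
        y = mish(grid)
        assert y.min() > -0.31
        pos = grid >= 0
        assert np.all(np.diff(y[pos]) >= 0)

    @given(st.floats(-30, 30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_gradient_matches_finite_difference(self, x):
        h = 1e-6
        num = (mish(x + h) - mish(x - h)) / (2 * h)
        assert mish_grad(np.array([x]))[0] == pytest.approx(num, abs=1e-4)


class TestSmoothLabels:
    def test_identity_at_zero_eps(self, toy_assignment):
        assert smooth_labels(toy_assignment, 0.0) is toy_assignment

    def test_one_hot_two_clusters(self, toy_assignment):
        out = smooth_labels(toy_assignment, 0.1)
        np.testing.assert_allclose(out.weights[0], [0.95, 0.05])
        np.testing.assert_allclose(out.weights.sum(axis=1), 1.0)
        assert not out.is_hard

    def test_soft_rows_left_untouched(self):
        soft = ClusterAssignment(
            weights=np.array([[0.5, 0.5], [0.3, 0.7]]),
            cluster_ids=["a", "b"],
            cell_ids=["c1", "c2"],
        )
        out = smooth_labels(soft, 0.2)
        np.testing.assert_array_equal(out.weights, soft.weights)

    @pytest.mark.parametrize("eps", [-0.1, 1.0, 1.5])
    def test_invalid_eps_rejected(self, toy_assignment, eps):
        with pytest.raises(ValueError):
            smooth_labels(toy_assignment, eps)


class TestRestrictLatent:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([1.0, 0.0], [1, 1, 0, 0]),
            ([0.5, 0.5], [0.5, 0.5, 0.5, 0.5]),
            ([1.0, 1.0], [1, 1, 1, 1]),
        ],
    )
    def test_block_gating(self, row, expected):
        out = restrict_latent(np.ones(4), np.asarray(row), units_per_cluster=2)
        np.testing.assert_allclose(out, expected)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            restrict_latent(np.ones(5), np.array([1.0, 0.0]), units_per_cluster=2)

    def test_zero_row_matches_zero_latent_decode(self, tiny_bifurcation, tiny_model_config):
        _, data, hard, _, _ = tiny_bifurcation
        model = train_model(data, hard, tiny_model_config)
        z = np.random.default_rng(0).normal(size=model.n_latent)
        masked = restrict_latent(z, np.zeros(hard.n_clusters), tiny_model_config.latent_units_per_cluster)
        np.testing.assert_allclose(model.decode(masked), model.decode(np.zeros_like(z)))


class TestVaeLoss:
    def test_zero_at_perfect_reconstruction_at_prior(self):
        x = np.array([1.0, 2.0])
        assert vae_loss(x, x, mu=np.array([0.3]), log_sigma=np.array([0.0]), s=0.3) == 0.0

    def test_derived_value(self):
        assert vae_loss([1.0], [0.0], [0.0], [0.0], s=0.0, alpha=2.0, beta=1.0) == pytest.approx(2.0)

    def test_alpha_linearity(self):
        args = ([1.0, 2.0], [0.0, 1.0], [0.5], [0.2])
        assert vae_loss(*args, alpha=2.0, beta=0.0) == pytest.approx(
            2 * vae_loss(*args, alpha=1.0, beta=0.0)
        )

    def test_beta_linearity(self):
        args = ([1.0], [1.0], [0.5, -0.2], [0.2, 0.4])
        assert vae_loss(*args, alpha=1.0, beta=2.0) == pytest.approx(
            2 * vae_loss(*args, alpha=1.0, beta=1.0)
        )

    def test_unit_weights_match_reference_formula(self):
        rng = np.random.default_rng(3)
        x, xr = rng.normal(size=6), rng.normal(size=6)
        mu, ls = rng.normal(size=4), rng.normal(size=4)
        s = 0.7
        ref_rec = float(np.sum((x - xr) ** 2))
        ref_kl = float(0.5 * np.sum(np.exp(ls) + (s - mu) ** 2 - 1.0 - ls))
        assert vae_loss(x, xr, mu, ls, s=s) == pytest.approx(ref_rec + ref_kl, rel=1e-12)
        assert ref_kl >= 0 or vae_loss(x, xr, mu, ls, s=s) >= 0

    def test_loss_non_negative(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            mu, ls = rng.normal(size=3), rng.normal(size=3)
            assert vae_loss([0.0], [0.0], mu, ls, s=float(rng.normal())) >= 0

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            vae_loss([np.nan], [0.0], [0.0], [0.0])


class TestInitializers:
    def test_pairing_is_enforced(self):
        assert init_for_activation("relu") is he_uniform
        assert init_for_activation("mish") is glorot_uniform
        with pytest.raises(ValueError):
            init_for_activation("tanh")

    def test_relu_grad(self):
        np.testing.assert_array_equal(relu_grad(np.array([-1.0, 0.0, 2.0])), [0, 0, 1])


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        """Analytic backprop agrees with central finite differences."""
        cfg = ModelConfig(
            epochs=1, encoder_units=5, decoder_units=6, latent_units_per_cluster=2, seed=0
        )
        rng = np.random.default_rng(1)
        n_feat, n_clusters = 4, 2
        n_latent = n_clusters * cfg.latent_units_per_cluster
        params = _init_params(rng, n_feat, n_latent, cfg)
        x = rng.normal(size=(3, n_feat)) ** 2
        mask = np.repeat(rng.uniform(0.2, 1.0, size=(3, n_clusters)), 2, axis=1)
        eps = rng.standard_normal((3, n_latent))
        _, grads = _batch_forward_backward(params, x, mask, eps, cfg)
        h = 1e-6
        for name in params:
            flat = params[name].reshape(-1)
            for idx in [0, flat.size // 2, flat.size - 1]:
                orig = flat[idx]
                flat[idx] = orig + h
                lp, _ = _batch_forward_backward(params, x, mask, eps, cfg)
                flat[idx] = orig - h
                lm, _ = _batch_forward_backward(params, x, mask, eps, cfg)
                flat[idx] = orig
                num = (lp - lm) / (2 * h)
                ana = grads[name].reshape(-1)[idx]
                assert ana == pytest.approx(num, abs=1e-5), name


class TestTrainModel:
    def test_deterministic_given_seed(self, tiny_bifurcation, tiny_model_config):
        _, data, hard, _, _ = tiny_bifurcation
        m1 = train_model(data, hard, tiny_model_config)
        m2 = train_model(data, hard, tiny_model_config)
        assert m1.final_loss == m2.final_loss
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_training_reduces_loss(self, tiny_bifurcation, tiny_model_config):
        _, data, hard, _, _ = tiny_bifurcation
        model = train_model(data, hard, tiny_model_config)
        assert model.final_loss < model.loss_history[0]
        n10 = max(1, len(model.loss_history) // 10)
        assert np.mean(model.loss_history[-n10:]) <= np.mean(model.loss_history[:n10])

    def test_soft_assignment_trains(self, tiny_bifurcation, tiny_model_config):
        _, data, _, soft, _ = tiny_bifurcation
        model = train_model(data, soft, tiny_model_config)
        assert np.isfinite(model.final_loss)

    def test_epochs_zero_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(epochs=0)

    def test_cell_mismatch_rejected(self, toy_matrix):
        bad = ClusterAssignment.from_labels(["a", "b"], ["x1", "x2"])
        with pytest.raises(ValueError):
            train_model(toy_matrix, bad, ModelConfig(epochs=1))

    def test_all_zero_matrix_rejected(self, toy_assignment):
        zeros = ExpressionMatrix(
            values=np.zeros((4, 2)), feature_ids=["g1", "g2"], cell_ids=["c1", "c2", "c3", "c4"]
        )
        with pytest.raises(ValueError):
            train_model(zeros, toy_assignment, ModelConfig(epochs=1))


def test_preprocess_normalizes_library_size():
    values = np.array([[10.0, 10.0], [1.0, 1.0]])
    out = preprocess(values, normalize=True)
    # both cells scaled to the median total, then log1p
    np.testing.assert_allclose(out[0], out[1])
    np.testing.assert_array_equal(preprocess(values, normalize=False), values)
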
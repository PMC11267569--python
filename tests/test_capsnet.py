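"""Capsule math: squash, prediction vectors, routing, lengths, loss,
forward composition and gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcgrcaps.capsnet import (CapsNet, CapsNetConfig, ConfigurationError,
                              capsule_lengths, compute_prediction_vectors,
                              dynamic_routing, margin_loss, scale_images,
                              squash, tiny_config)
from fcgrcaps.estimators import CapsNetClassifier

from oracles import naive_capsnet_forward, naive_squash

vectors = st.lists(st.floats(-5, 5), min_size=1, max_size=8).map(np.array)


class TestSquash:
    def test_zero_maps_to_zero_exactly(self):
        out = squash(np.zeros(5))
        assert np.array_equal(out, np.zeros(5))

    def test_unit_vector_halves(self):
        u = np.array([1.0, 0.0, 0.0])
        assert np.allclose(squash(u), 0.5 * u)

    def test_three_four_worked_example(self):
        out = squash(np.array([3.0, 4.0]))
        assert np.allclose(out, [15 / 26, 20 / 26])
        assert np.isclose(np.linalg.norm(out), 25 / 26)

    @given(vectors)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_norm_identity_and_bound(self, s):
        a = np.linalg.norm(s)
        out = squash(s)
        assert np.isclose(np.linalg.norm(out), a * a / (1 + a * a), atol=1e-12)
        assert np.linalg.norm(out) < 1.0
        assert np.allclose(out, naive_squash(s), atol=1e-12)

    def test_monotone_in_input_norm(self):
        u = np.array([1.0, 1.0]) / np.sqrt(2)
        norms = [np.linalg.norm(squash(t * u)) for t in (0.1, 0.5, 1.0, 3.0, 10.0)]
        assert np.all(np.diff(norms) > 0)


class TestPredictionVectors:
    def test_zero_weights_give_zero_predictions(self):
        u = np.ones((4, 3))
        W = np.zeros((4, 2, 5, 3))
        assert np.array_equal(compute_prediction_vectors(u, W), np.zeros((4, 2, 5)))

    def test_identity_weights_pass_capsules_through(self):
        u = np.arange(6.0).reshape(3, 2)
        W = np.broadcast_to(np.eye(2), (3, 2, 2, 2)).copy()
        u_hat = compute_prediction_vectors(u, W)
        for j in range(2):
            assert np.array_equal(u_hat[:, j, :], u)

    def test_matches_hand_matrix_vector_products(self, rng):
        u = rng.normal(size=(3, 2))
        W = rng.normal(size=(3, 2, 2, 2))
        u_hat = compute_prediction_vectors(u, W)
        for i in range(3):
            for j in range(2):
                assert np.allclose(u_hat[i, j], W[i, j] @ u[i])

    def test_shape_mismatch_names_dimensions(self):
        with pytest.raises(ConfigurationError, match="shape mismatch"):
            compute_prediction_vectors(np.ones((4, 3)), np.zeros((4, 2, 5, 7)))


class TestRouting:
    def test_zero_logits_give_uniform_coupling(self, rng):
        u_hat = rng.normal(size=(5, 2, 3))
        _, c = dynamic_routing(u_hat, r=1)
        assert np.allclose(c, 0.5)

    def test_single_capsule_one_iteration_worked_example(self, rng):
        v = rng.normal(size=3)
        u_hat = np.stack([v, v])[None]            # L=1, J=2
        V, c = dynamic_routing(u_hat, r=1)
        for j in range(2):
            assert np.allclose(V[j], squash(0.5 * v))

    def test_coupling_is_a_distribution_at_every_iteration(self, rng):
        u_hat = rng.normal(size=(6, 2, 4))
        _, _, cache = dynamic_routing(u_hat, r=4, return_cache=True)
        assert len(cache) == 4
        for c_t, _, _ in cache:
            assert np.all(c_t >= 0)
            assert np.allclose(c_t.sum(axis=-1), 1.0)

    def test_rejects_bad_iterations_and_nonfinite_input(self, rng):
        u_hat = rng.normal(size=(2, 2, 2))
        with pytest.raises(ConfigurationError):
            dynamic_routing(u_hat, r=0)
        u_hat[0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            dynamic_routing(u_hat, r=2)

    def test_permutation_of_primary_capsules_leaves_output_invariant(self, rng):
        u = rng.normal(size=(6, 3))
        W = rng.normal(size=(6, 2, 4, 3))
        V1, _ = dynamic_routing(compute_prediction_vectors(u, W), r=3)
        perm = rng.permutation(6)
        V2, _ = dynamic_routing(compute_prediction_vectors(u[perm], W[perm]), r=3)
        assert np.allclose(V1, V2, atol=1e-12)


class TestLengthsAndLoss:
    def test_three_four_five_length(self):
        assert np.isclose(capsule_lengths(np.array([0.3, 0.4])), 0.5)
        assert capsule_lengths(np.zeros(4)) == 0.0

    def test_post_squash_lengths_below_one(self, rng):
        V = squash(rng.normal(size=(10, 8)) * 100)
        assert np.all(capsule_lengths(V) < 1.0)

    @pytest.mark.parametrize("p,label,expected", [
        ((0.9, 0.1), 0, 0.0),
        ((1.0, 0.0), 0, 0.0),
        ((0.5, 0.5), 0, 0.24),
    ])
    def test_margin_loss_hand_values(self, p, label, expected):
        assert np.isclose(margin_loss(np.array(p), label), expected)

    def test_margin_loss_batched(self):
        losses = margin_loss(np.array([[0.9, 0.1], [0.5, 0.5]]), [0, 0])
        assert np.allclose(losses, [0.0, 0.24])


class TestForward:
    def test_zero_image_zero_params_propagates_to_zero_probabilities(self):
        cfg = tiny_config()
        net = CapsNet(cfg, rng=np.random.default_rng(0))
        for k in net.params:
            net.params[k] = np.zeros_like(net.params[k])
        out = net.forward(np.zeros((1, 8, 8)))
        assert np.array_equal(out["p"], np.zeros((1, 2)))

    def test_forward_is_deterministic(self, tiny_net, rng):
        X = rng.random((2, 8, 8))
        p1 = tiny_net.forward(X)["p"]
        p2 = tiny_net.forward(X)["p"]
        assert np.array_equal(p1, p2)

    def test_forward_matches_straightline_oracle(self, rng):
        cfg = tiny_config(n=2, routing_iterations=2)
        net = CapsNet(cfg, rng=np.random.default_rng(5))
        X = rng.random((3, 8, 8))
        out = net.forward(X)
        for b in range(3):
            p_ref, V_ref, u_ref = naive_capsnet_forward(X[b], net.params, cfg)
            assert np.allclose(out["p"][b], p_ref, atol=1e-10)
            assert np.allclose(out["V"][b], V_ref, atol=1e-10)
            assert np.allclose(out["u"][b], u_ref, atol=1e-10)

    def test_resolution_mismatch_is_a_configuration_error(self, tiny_net):
        with pytest.raises(ConfigurationError, match="resolution"):
            tiny_net.forward(np.zeros((1, 16, 16)))

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            CapsNetConfig(input_resolution=4)  # 9x9 kernel cannot fit
        with pytest.raises(ConfigurationError):
            tiny_config(frontend_filters=0)


class TestGradients:
    def test_margin_loss_gradients_match_finite_differences(self, rng):
        net = CapsNet(tiny_config(), rng=np.random.default_rng(3))
        X = rng.random((2, 8, 8))
        y = np.array([0, 1])
        _, grads = net.loss_and_grads(X, y)
        eps = 1e-6
        check_rng = np.random.default_rng(0)
        for name, arr in net.params.items():
            for flat_i in check_rng.choice(arr.size, size=min(8, arr.size), replace=False):
                idx = np.unravel_index(flat_i, arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = net.loss_and_grads(X, y)
                arr[idx] = orig - eps
                lm, _ = net.loss_and_grads(X, y)
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grads[name][idx]) <= 1e-4 * max(1.0, abs(fd)), name


class TestInputScaling:
    def test_per_max_bounds_images_to_unit_interval(self, rng):
        X = rng.integers(0, 20, size=(3, 4, 4)).astype(float)
        Xs = scale_images(X, "per_max")
        assert Xs.max() <= 1.0
        assert np.allclose(Xs.max(axis=(1, 2)), 1.0)

    def test_all_zero_image_stays_zero(self):
        assert np.array_equal(scale_images(np.zeros((1, 4, 4)), "per_max"),
                              np.zeros((1, 4, 4)))


class TestTrainingContract:
    def test_zero_epochs_returns_initialization(self, rng):
        X = rng.random((8, 8, 8))
        y = np.array([0, 1] * 4)
        clf = CapsNetClassifier(config=tiny_config(), n_epochs=0, random_state=1)
        clf.fit(X, y)
        ref = CapsNet(tiny_config(), rng=np.random.default_rng(1))
        for k in ref.params:
            assert np.array_equal(clf.net_.params[k], ref.params[k])

    def test_same_seed_reproduces_final_loss(self, rng):
        X = rng.random((12, 8, 8))
        y = np.array([0, 1] * 6)
        runs = [CapsNetClassifier(config=tiny_config(), n_epochs=3, random_state=5)
                .fit(X, y).loss_curve_ for _ in range(2)]
        assert runs[0] == runs[1]
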
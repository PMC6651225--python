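"""Capsule mechanics: squash, routing vs loop oracle, losses, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import capsmi as cm
from capsmi.capsnet import (
    CapsNetModel,
    finite_difference_check,
    init_params,
    load_checkpoint,
    predict,
    save_checkpoint,
)

from .oracles import prediction_vectors_loop, routing_loop


class TestSelu:
    def test_fixed_points(self):
        assert cm.selu(0.0) == 0.0
        assert cm.selu(2.0) == pytest.approx(2 * 1.0507, rel=1e-6)

    def test_negative_limit(self):
        assert cm.selu(-50.0) == pytest.approx(-1.0507 * 1.6733, rel=1e-4)

    def test_elementwise_on_arrays(self):
        x = np.array([-1.0, 0.0, 1.0])
        out = cm.selu(x)
        assert out.shape == x.shape
        assert out[2] == pytest.approx(1.0507)


class TestSquash:
    @pytest.mark.parametrize("norm,expected", [(1.0, 0.5), (3.0, 0.9)])
    def test_norm_mapping(self, norm, expected):
        s = np.array([norm, 0.0, 0.0])
        v = cm.squash(s)
        assert np.linalg.norm(v) == pytest.approx(expected)
        assert np.allclose(np.cross(v, s), 0.0)  # parallel

    def test_zero_maps_to_zero(self):
        np.testing.assert_array_equal(cm.squash(np.zeros(4)), 0.0)

    @given(arrays(np.float64, 4, elements=st.floats(-5, 5)))
    @settings(max_examples=50, deadline=None)
    def test_norm_below_one_and_monotone(self, s):
        v = cm.squash(s)
        assert np.linalg.norm(v) < 1.0
        bigger = cm.squash(1.5 * s)
        assert np.linalg.norm(bigger) >= np.linalg.norm(v) - 1e-12


class TestCouplingSoftmax:
    def test_closed_forms(self):
        np.testing.assert_allclose(cm.coupling_softmax([0.0, 0.0]), [0.5, 0.5])
        np.testing.assert_allclose(cm.coupling_softmax([np.log(2), 0.0]), [2 / 3, 1 / 3])

    @given(arrays(np.float64, (5, 2), elements=st.floats(-15, 15)))
    @settings(max_examples=50, deadline=None)
    def test_rows_sum_to_one_in_open_interval(self, b):
        c = cm.coupling_softmax(b)
        np.testing.assert_allclose(c.sum(axis=-1), 1.0, atol=1e-12)
        assert np.all((c > 0) & (c < 1))


class TestPredictionVectors:
    def test_identity_and_zero_weights(self):
        u = np.arange(8.0).reshape(2, 4)
        W_id = np.broadcast_to(np.eye(4), (2, 2, 4, 4)).copy()
        np.testing.assert_allclose(cm.prediction_vectors(u, W_id)[:, 0], u)
        np.testing.assert_array_equal(cm.prediction_vectors(u, np.zeros((2, 2, 4, 4))), 0.0)

    def test_matches_per_pair_loop(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(6, 3))
        W = rng.normal(size=(6, 2, 5, 3))
        np.testing.assert_allclose(
            cm.prediction_vectors(u, W), prediction_vectors_loop(u, W), atol=1e-12
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cm.prediction_vectors(np.zeros((2, 3)), np.zeros((2, 2, 5, 4)))


class TestDynamicRouting:
    def test_single_iteration_is_uniform_coupling(self):
        rng = np.random.default_rng(1)
        u_hat = rng.normal(size=(7, 2, 8))
        v, c, _ = cm.dynamic_routing(u_hat, r=1)
        np.testing.assert_allclose(c, 0.5)
        expected = cm.squash(u_hat.mean(axis=0) * u_hat.shape[0] / 2, axis=-1)
        np.testing.assert_allclose(v, expected, atol=1e-12)

    @pytest.mark.parametrize("n_in,r", [(2, 3), (5, 2), (10, 3)])
    def test_matches_straight_loop_oracle(self, n_in, r):
        rng = np.random.default_rng(n_in * 10 + r)
        u_hat = rng.normal(size=(n_in, 2, 4))
        v, c, _ = cm.dynamic_routing(u_hat, r=r)
        v_o, c_o = routing_loop(u_hat, r)
        np.testing.assert_allclose(v, v_o, atol=1e-10)
        np.testing.assert_allclose(c, c_o, atol=1e-10)

    def test_agreement_routes_to_larger_prediction(self):
        # identical predictions per class with |u_hat_1| > |u_hat_2|:
        # routing concentrates coupling on class 1
        u_hat = np.zeros((4, 2, 3))
        u_hat[:, 0] = [2.0, 0.0, 0.0]
        u_hat[:, 1] = [0.5, 0.0, 0.0]
        _, c, _ = cm.dynamic_routing(u_hat, r=3)
        assert np.all(c[:, 0] > c[:, 1])

    def test_coupling_conservation_each_iteration(self):
        rng = np.random.default_rng(2)
        u_hat = rng.normal(size=(8, 2, 4))
        for r in (1, 2, 3):
            _, c, _ = cm.dynamic_routing(u_hat, r=r)
            np.testing.assert_allclose(c.sum(axis=-1), 1.0, atol=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        u_hat = rng.normal(size=(6, 2, 4))
        perm = rng.permutation(6)
        v, _, _ = cm.dynamic_routing(u_hat, r=3)
        v_p, _, _ = cm.dynamic_routing(u_hat[perm], r=3)
        np.testing.assert_allclose(v, v_p, atol=1e-12)

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            cm.dynamic_routing(np.zeros((2, 2, 4)), r=0)


class TestLosses:
    def test_margin_loss_inactive_at_confident_correct(self):
        # target norm above m+ and other norm below m-: both hinges inactive
        assert cm.margin_loss([0.95, 0.05], [1, 0]) == 0.0

    def test_margin_loss_hand_example(self):
        # (0.9-0.5)^2 + 0.5*(0.5-0.1)^2 = 0.24
        assert cm.margin_loss([0.5, 0.5], [0, 1]) == pytest.approx(0.24)

    def test_margin_loss_monotonicity(self):
        base = cm.margin_loss([0.5, 0.5], [0, 1])
        assert cm.margin_loss([0.5, 0.6], [0, 1]) <= base  # target norm up
        assert cm.margin_loss([0.6, 0.5], [0, 1]) >= base  # other norm up

    def test_total_loss_combination(self):
        assert cm.total_loss(0.24, 100.0) == pytest.approx(0.29)
        assert cm.total_loss(0.24, 0.0) == pytest.approx(0.24)
        cfg = cm.CapsNetConfig(reconstruction=False)
        assert cm.total_loss(0.24, 1e6, cfg) == pytest.approx(0.24)

    @pytest.mark.parametrize("norms,expected", [
        ([0.9, 0.1], 0), ([0.1, 0.9], 1), ([0.5, 0.5], 0),
    ])
    def test_predict_argmax_low_index_ties(self, norms, expected):
        assert predict(norms) == expected


class TestForwardPass:
    def test_architecture_shapes(self, small_images):
        cfg = cm.CapsNetConfig()
        assert cfg.conv_out == 12
        assert cfg.primary_grid == 5
        assert cfg.n_primary_caps == 3200
        model = CapsNetModel(cfg, seed=0)
        norms, v, recon, state = model.forward(small_images[0][:2])
        assert norms.shape == (2, 2)
        assert v.shape == (2, 2, 8)
        assert recon.shape == (2, 588)
        assert state.u.shape == (2, 3200, 4)
        assert state.u_hat.shape == (2, 3200, 2, 8)
        assert np.all(norms < 1.0) and np.all(norms >= 0.0)
        assert np.all((recon > 0) & (recon < 1))

    def test_zero_image_zero_bias_gives_zero_norms(self):
        model = CapsNetModel(seed=0)
        for k in ("conv_b", "prim_b"):
            model.params[k][:] = 0.0
        norms, *_ = model.forward(np.zeros((1, 3, 14, 14)))
        np.testing.assert_allclose(norms, 0.0, atol=1e-12)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            CapsNetModel(seed=0).forward(np.zeros((1, 3, 10, 10)))

    def test_coupling_conservation_in_state(self, small_images):
        model = CapsNetModel(cm.CapsNetConfig(routing_iters=3), seed=0)
        *_, state = model.forward(small_images[0][:2])
        np.testing.assert_allclose(state.c.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(np.linalg.norm(state.v, axis=-1) < 1.0)


class TestDecoder:
    def test_output_length_and_range(self, small_images):
        model = CapsNetModel(seed=0)
        v = np.random.default_rng(0).normal(size=(2, 2, 8))
        mask = np.array([[1.0, 0.0], [0.0, 1.0]])
        recon = model.decoder_reconstruct(v, mask)
        assert recon.shape == (2, 588)
        assert np.all((recon > 0) & (recon < 1))

    def test_masked_capsule_has_no_effect(self):
        model = CapsNetModel(seed=0)
        rng = np.random.default_rng(1)
        v = rng.normal(size=(1, 2, 8))
        mask = np.array([[1.0, 0.0]])
        base = model.decoder_reconstruct(v, mask)
        v2 = v.copy()
        v2[0, 1] = rng.normal(size=8)  # change only the non-selected capsule
        np.testing.assert_array_equal(model.decoder_reconstruct(v2, mask), base)

    def test_non_onehot_mask_rejected(self):
        model = CapsNetModel(seed=0)
        with pytest.raises(ValueError, match="one-hot"):
            model.decoder_reconstruct(np.zeros((1, 2, 8)), np.array([[0.5, 0.5]]))


class TestGradients:
    @pytest.mark.parametrize("routing_iters,reconstruction", [
        (1, True), (2, True), (3, True), (1, False),
    ])
    def test_finite_difference_agreement(self, small_images, routing_iters, reconstruction):
        cfg = cm.CapsNetConfig(routing_iters=routing_iters, reconstruction=reconstruction)
        model = CapsNetModel(cfg, seed=0, dtype=np.float64)
        X, y = small_images
        err = finite_difference_check(
            model, X[:3], y[:3], n_entries=3, step=1e-5, seed=routing_iters
        )
        assert err < 1e-4


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, small_images, tmp_path):
        model = CapsNetModel(seed=3)
        path = str(tmp_path / "model.npz")
        save_checkpoint(path, model)
        loaded = load_checkpoint(path)
        assert loaded.cfg == model.cfg
        X = small_images[0][:4]
        np.testing.assert_allclose(loaded.forward(X)[0], model.forward(X)[0], atol=1e-7)

    def test_init_is_seeded(self):
        a = init_params(cm.CapsNetConfig(), seed=5)
        b = init_params(cm.CapsNetConfig(), seed=5)
        c = init_params(cm.CapsNetConfig(), seed=6)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])
        assert any(not np.array_equal(a[k], c[k]) for k in a)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"routing_iters": 0},
        {"m_plus": 0.05, "m_minus": 0.1},
        {"lambda_rec": 0.0},
        {"decoder_sizes": (512, 1024, 500)},
        {"conv_kernel": 20},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cm.CapsNetConfig(**kwargs)
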
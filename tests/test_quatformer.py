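import warnings

import numpy as np
import pytest
from scipy.special import softmax

from ricestore.quatformer import (GlobalMemory, Quatformer, QuatformerConfig,
                                  RotationParams, _RotationLearner,
                                  decoupled_lra, lra_attention, lra_scores,
                                  omega_regularizer, rotate_pairs,
                                  score_counter, theta_regularizer,
                                  total_loss, trend_normalize)
from ricestore.autodiff import Tensor


def plain_attention(q, k, v):
    """Independent oracle: standard scaled dot-product attention."""
    return softmax(q @ k.T / np.sqrt(q.shape[-1]), axis=-1) @ v


class TestRotatePairs:
    def test_zero_angle_is_identity(self, rng):
        x = rng.normal(size=(5, 6))
        assert np.allclose(rotate_pairs(x, np.zeros((3, 5))), x)

    def test_quarter_turn_maps_e1_to_e2(self):
        out = rotate_pairs(np.array([[1.0, 0.0]]), np.array([[np.pi / 2]]))
        assert np.allclose(out, [[0.0, 1.0]], atol=1e-12)

    def test_rotations_preserve_position_norms(self, rng):
        x = rng.normal(size=(7, 8))
        ang = rng.uniform(-np.pi, np.pi, size=(4, 7))
        out = rotate_pairs(x, ang)
        assert np.allclose(np.linalg.norm(out, axis=1),
                           np.linalg.norm(x, axis=1), atol=1e-9)

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError):
            rotate_pairs(np.zeros((2, 3)), np.zeros((1, 2)))

    def test_composition_equals_angle_sum(self, rng):
        x = rng.normal(size=(4, 2))
        a1 = rng.uniform(-1, 1, size=(1, 4))
        a2 = rng.uniform(-1, 1, size=(1, 4))
        assert np.allclose(rotate_pairs(rotate_pairs(x, a1), a2),
                           rotate_pairs(x, a1 + a2), atol=1e-12)


class TestRotationLearner:
    def test_constant_input_gives_constant_params(self, rng):
        learner = _RotationLearner(np.random.default_rng(0), 8)
        x = Tensor(np.tile(rng.normal(size=(1, 8)), (6, 1)))
        omega, theta = learner(x)
        assert np.allclose(omega.data, omega.data[:, :1])
        assert np.allclose(theta.data, theta.data[:, :1])

    def test_omega_within_nyquist_band(self, rng):
        learner = _RotationLearner(np.random.default_rng(0), 8)
        omega, theta = learner(Tensor(rng.normal(size=(10, 8)) * 50))
        assert np.all(omega.data >= 0) and np.all(omega.data <= 0.5)
        assert np.all(np.abs(theta.data) <= np.pi)

    def test_output_shapes(self, rng):
        learner = _RotationLearner(np.random.default_rng(0), 8)
        omega, theta = learner(Tensor(rng.normal(size=(3, 9, 8))))
        assert omega.shape == (3, 4, 9) and theta.shape == (3, 4, 9)


class TestLraScores:
    def test_zero_vectors_score_one(self):
        P, N = 2, 3
        z = np.zeros((N, 4))
        s = lra_scores(z, z, RotationParams.zero(P, N),
                       RotationParams.zero(P, N))
        assert np.allclose(s, 1.0)

    def test_quarter_period_orthogonality(self):
        # q=(1,0) at position 1 with omega=1/4 turns it to (0,1); the key
        # (1,0) is unrotated, so the inner product and hence log-score is 0
        q = np.array([[0.0, 0.0], [1.0, 0.0]])
        k = np.array([[1.0, 0.0]])
        rp_q = RotationParams(np.full((1, 2), 0.25), np.zeros((1, 2)))
        rp_k = RotationParams.zero(1, 1)
        s = lra_scores(q, k, rp_q, rp_k)
        assert s[1, 0] == pytest.approx(1.0, abs=1e-12)

    def test_shared_constant_omega_gives_relative_position_scores(self, rng):
        # brute force: with a shared constant frequency and zero phase the
        # score between fixed vectors depends only on m - n
        d_h, N = 4, 6
        x = rng.normal(size=d_h)
        q = np.tile(x, (N, 1))
        omega = np.full((d_h // 2, N), 0.11)
        rp = RotationParams(omega, np.zeros((d_h // 2, N)))
        s = lra_scores(q, q, rp, rp)
        for m in range(N):
            for n in range(N):
                for m2 in range(N):
                    n2 = m2 - (m - n)
                    if 0 <= n2 < N:
                        assert s[m, n] == pytest.approx(s[m2, n2], rel=1e-9)

    def test_positive_and_plane_count_checked(self, rng):
        q = rng.normal(size=(3, 4))
        s = lra_scores(q, q, RotationParams.zero(2, 3),
                       RotationParams.zero(2, 3))
        assert np.all(s > 0)
        with pytest.raises(ValueError):
            lra_scores(q, q, RotationParams.zero(3, 3),
                       RotationParams.zero(2, 3))


class TestLraAttention:
    def test_single_key_value_returns_value(self, rng):
        q = rng.normal(size=(4, 6))
        k = rng.normal(size=(1, 6))
        v = rng.normal(size=(1, 6))
        assert np.allclose(lra_attention(q, k, v), np.tile(v, (4, 1)))

    def test_identical_values_collapse(self, rng):
        q = rng.normal(size=(4, 6))
        k = rng.normal(size=(5, 6))
        v = np.tile(rng.normal(size=(1, 6)), (5, 1))
        assert np.allclose(lra_attention(q, k, v), np.tile(v[:1], (4, 1)),
                           atol=1e-9)

    def test_zero_rotation_equals_plain_attention(self, rng):
        q, k, v = (rng.normal(size=(6, 8)), rng.normal(size=(9, 8)),
                   rng.normal(size=(9, 8)))
        out = lra_attention(q, k, v)
        assert np.allclose(out, plain_attention(q, k, v), atol=1e-6)

    def test_weight_rows_are_probabilities(self, rng):
        q, k = rng.normal(size=(5, 4)), rng.normal(size=(7, 4))
        rp_q = RotationParams(rng.uniform(0, 0.5, (2, 5)),
                              rng.uniform(-3, 3, (2, 5)))
        rp_k = RotationParams(rng.uniform(0, 0.5, (2, 7)),
                              rng.uniform(-3, 3, (2, 7)))
        s = lra_scores(q, k, rp_q, rp_k)
        w = s / s.sum(axis=-1, keepdims=True)
        assert np.all(s > 0)
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-9)

    def test_empty_keys_rejected(self, rng):
        with pytest.raises(ValueError):
            lra_attention(rng.normal(size=(2, 4)), np.zeros((0, 4)),
                          np.zeros((0, 4)))


class TestDecoupledLra:
    def test_score_evaluation_count_is_linear(self, rng):
        mem = GlobalMemory(rng.normal(size=(4, 8)))
        score_counter.reset()
        decoupled_lra(rng.normal(size=(10, 8)), rng.normal(size=(10, 8)), mem)
        assert score_counter.count == 80  # N*c + c*L = 40 + 40

    @pytest.mark.parametrize("N,L,c", [(5, 7, 2), (12, 3, 5), (1, 1, 1)])
    def test_count_formula_across_sizes(self, rng, N, L, c):
        mem = GlobalMemory(rng.normal(size=(c, 6)))
        score_counter.reset()
        decoupled_lra(rng.normal(size=(N, 6)), rng.normal(size=(L, 6)), mem)
        assert score_counter.count == N * c + c * L

    def test_single_slot_memory_collapses_queries(self, rng):
        mem = GlobalMemory(rng.normal(size=(1, 6)))
        out = decoupled_lra(rng.normal(size=(5, 6)), rng.normal(size=(4, 6)),
                            mem)
        assert np.allclose(out.H, np.tile(out.M_prime, (5, 1)))

    def test_output_shapes(self, rng):
        mem = GlobalMemory(rng.normal(size=(3, 6)))
        out = decoupled_lra(rng.normal(size=(5, 6)), rng.normal(size=(7, 6)),
                            mem)
        assert out.H.shape == (5, 6) and out.M_prime.shape == (3, 6)

    def test_empty_memory_rejected(self):
        with pytest.raises(ValueError):
            GlobalMemory(np.zeros((0, 4)))


class TestTrendNormalize:
    def test_linear_input_passes_through(self):
        t = np.arange(8.0)[:, None]
        x = 3.0 * t + 1.0 + np.zeros((8, 4))
        assert np.allclose(trend_normalize(x), x, atol=1e-6)

    def test_constant_input_passes_through(self):
        x = np.full((6, 3), 2.5)
        assert np.allclose(trend_normalize(x), x, atol=1e-6)

    def test_detrended_output_has_zero_slope(self, rng):
        x = rng.normal(size=(20, 5))
        t = np.arange(20.0)
        X = np.stack([np.ones(20), t], axis=1)
        trend = X @ np.linalg.lstsq(X, x, rcond=None)[0]
        out = trend_normalize(x)  # rho=1: subtract the trend back out
        resid = out - trend
        slopes = np.linalg.lstsq(X, resid, rcond=None)[0][1]
        assert np.allclose(slopes, 0.0, atol=1e-8)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            trend_normalize(np.zeros((1, 3)))


class TestRegularizers:
    def test_omega_hand_values(self):
        assert omega_regularizer(np.array([[0.0, 1.0, 3.0]])) == pytest.approx(2.5)
        assert omega_regularizer(np.array([[0.0, 1.0], [0.0, 2.0]])) == \
            pytest.approx(2.5)
        assert omega_regularizer(np.full((3, 4), 0.2)) == 0.0

    def test_theta_hand_values(self):
        assert theta_regularizer(np.array([[1.0, -1.0]])) == pytest.approx(1.0)
        assert theta_regularizer(np.array([[2.0], [-4.0]])) == pytest.approx(3.0)
        assert theta_regularizer(np.zeros((2, 5))) == 0.0

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValueError):
            omega_regularizer(np.zeros((2, 1)))
        with pytest.raises(ValueError):
            theta_regularizer(np.zeros((2, 0)))


class TestTotalLoss:
    def test_reduces_to_mse_without_penalties(self, rng):
        p, t = rng.normal(size=5), rng.normal(size=5)
        assert total_loss(p, t) == pytest.approx(np.mean((p - t) ** 2))

    def test_arithmetic_combination(self):
        # L_pred = 1, L_omega = 2, L_theta = 3 -> 1 + 0.5*2 + 0.1*3 = 2.3
        pred, target = np.array([2.0]), np.array([1.0])
        omega = np.array([[0.0, 2.0]])          # mean sq diff = 4 ... need 2
        omega = np.array([[0.0, np.sqrt(2.0)]])  # (sqrt2)^2 / 1 = 2
        theta = np.array([[3.0]])
        assert total_loss(pred, target, [omega], [theta], 0.5, 0.1) == \
            pytest.approx(2.3)

    def test_perfect_prediction_zero_params(self):
        y = np.array([1.0, 2.0])
        assert total_loss(y, y, [np.zeros((1, 3))], [np.zeros((1, 3))],
                          0.7, 0.7) == 0.0

    def test_loss_decomposition_identity(self, rng):
        pred, target = rng.normal(size=6), rng.normal(size=6)
        oms = [rng.uniform(0, 0.5, (2, 5)) for _ in range(3)]
        ths = [rng.uniform(-2, 2, (2, 5)) for _ in range(3)]
        l1, l2 = 0.013, 0.021
        total = total_loss(pred, target, oms, ths, l1, l2)
        l_pred = np.mean((pred - target) ** 2)
        l_om = np.mean([omega_regularizer(o) for o in oms])
        l_th = np.mean([theta_regularizer(t) for t in ths])
        assert total - l_pred == pytest.approx(l1 * l_om + l2 * l_th,
                                               abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            total_loss(np.zeros(3), np.zeros(4))


class TestQuatformerModel:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            QuatformerConfig(d_model=30, n_heads=4)
        with pytest.raises(ValueError):
            QuatformerConfig(lambda1=-0.1)

    def test_forecast_output_length_matches_horizon(self):
        cfg = QuatformerConfig(d_model=8, n_heads=2, memory_len=2, horizon=1)
        model = Quatformer(cfg)
        with pytest.warns(UserWarning, match="untrained"):
            out = model.forecast(np.ones((7, 3)))
        assert out.shape == (1,)

    def test_zeroed_head_outputs_destandardized_bias(self):
        cfg = QuatformerConfig(d_model=8, n_heads=2, memory_len=2)
        model = Quatformer(cfg)
        model.head_w.data[:] = 0.0
        model.head_b.data[:] = 0.25
        model.set_scaler(2.0, 4.0, np.zeros(2), np.ones(2))
        model.trained = True
        out = model.forecast(np.ones((7, 3)))
        assert out[0] == pytest.approx(0.25 * 4.0 + 2.0)

    def test_save_load_roundtrip(self, tmp_path, rng):
        cfg = QuatformerConfig(d_model=8, n_heads=2, memory_len=2, seed=5)
        model = Quatformer(cfg)
        model.trained = True
        w = rng.uniform(1.0, 2.0, size=(7, 3))
        before = model.forecast(w)
        path = tmp_path / "ckpt.json"
        model.save(path)
        loaded = Quatformer.load(path)
        assert np.allclose(loaded.forecast(w), before, atol=1e-12)
        assert loaded.config == cfg
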
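"""Rotary embedding and encoder mathematics against brute-force oracles."""

import numpy as np
import pytest

from emgkin.rope import (
    AttentionConfig,
    attention_weights,
    encoder_forward,
    init_encoder_weights,
    layer_norm,
    mish,
    multi_head_attention,
    rope_rotate,
    scaled_dot_attention,
)


from _oracles import attention_oracle, encoder_oracle, rotate_oracle


class TestRopeRotate:
    def test_zero_vector_stays_zero(self):
        out = rope_rotate(np.zeros((3, 8)), [0, 5, 11])
        assert np.allclose(out, 0)

    def test_position_zero_is_identity(self, rng):
        v = rng.normal(size=(1, 8))
        assert np.allclose(rope_rotate(v, [0]), v)

    def test_matches_rotation_matrix_oracle(self, rng):
        for d in (4, 8):
            v = rng.normal(size=d)
            for m in (1, 7, 50):
                got = rope_rotate(v[None, :], [m])[0]
                want = rotate_oracle(v, m)
                assert np.allclose(got, want, atol=1e-10)

    def test_norm_preserved(self, rng):
        v = rng.normal(size=(20, 8))
        out = rope_rotate(v, np.arange(20))
        assert np.allclose(np.linalg.norm(out, axis=1),
                           np.linalg.norm(v, axis=1), atol=1e-6)

    def test_relative_position_invariance(self, rng):
        """<R_m q, R_n k> depends only on m - n."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            for d in (4, 8):
                q, k = r.normal(size=d), r.normal(size=d)
                for m, n, s in [(2, 5, 7), (0, 9, 3), (4, 4, 20)]:
                    a = rotate_oracle(q, m) @ rotate_oracle(k, n)
                    b = (rope_rotate(q[None], [m + s])[0]
                         @ rope_rotate(k[None], [n + s])[0])
                    assert np.isclose(a, b, atol=1e-6)

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError, match="even"):
            rope_rotate(np.zeros((2, 5)), [0, 1])


class TestScaledDotAttention:
    def test_single_position_returns_value_row(self, rng):
        Q = rng.normal(size=(1, 4))
        K = rng.normal(size=(1, 4))
        V = rng.normal(size=(1, 4))
        assert np.allclose(scaled_dot_attention(Q, K, V), V)

    def test_identical_keys_give_column_mean(self, rng):
        Q = rng.normal(size=(3, 4))
        K = np.tile(rng.normal(size=(1, 4)), (5, 1))
        V = rng.normal(size=(5, 4))
        out = scaled_dot_attention(Q, K, V)
        assert np.allclose(out, V.mean(axis=0), atol=1e-12)

    def test_matches_double_loop_oracle(self):
        r = np.random.default_rng(42)
        Q = r.normal(size=(2, 2))
        K = r.normal(size=(2, 2))
        V = r.normal(size=(2, 2))
        assert np.allclose(scaled_dot_attention(Q, K, V),
                           attention_oracle(Q, K, V), atol=1e-8)

    def test_rows_sum_to_one(self, rng):
        W = attention_weights(rng.normal(size=(6, 4)), rng.normal(size=(6, 4)))
        assert np.allclose(W.sum(axis=-1), 1.0, atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            scaled_dot_attention(rng.normal(size=(2, 4)),
                                 rng.normal(size=(2, 3)),
                                 rng.normal(size=(2, 3)))


def _mha_weights(cfg, rng):
    return {
        "heads": [rng.normal(size=(cfg.d_model, 3 * cfg.d_head))
                  for _ in range(cfg.n_heads)],
        "w_msa": rng.normal(size=(cfg.d_model, cfg.d_model)),
    }


class TestMultiHeadAttention:
    def test_single_head_reduces_to_scaled_dot(self, rng):
        cfg = AttentionConfig(d_model=4, n_heads=1, n_layers=1)
        w = _mha_weights(cfg, rng)
        Z = rng.normal(size=(5, 4))
        got = multi_head_attention(Z, cfg, w, use_rope=False)
        qkv = Z @ w["heads"][0]
        want = scaled_dot_attention(qkv[:, :4], qkv[:, 4:8], qkv[:, 8:]) @ w["w_msa"]
        assert np.allclose(got, want, atol=1e-12)

    def test_identity_like_weights_hand_computed(self):
        # one head, W_qkv stacks three identities, W_msa = I: output is
        # plain softmax attention of Z with itself
        cfg = AttentionConfig(d_model=4, n_heads=1, n_layers=1)
        w = {"heads": [np.hstack([np.eye(4)] * 3)], "w_msa": np.eye(4)}
        Z = np.array([[1.0, 0, 0, 0], [0, 2.0, 0, 0]])
        got = multi_head_attention(Z, cfg, w, use_rope=False)
        want = attention_oracle(Z, Z, Z)
        assert np.allclose(got, want, atol=1e-8)

    def test_permutation_contrast(self, rng):
        """RoPE breaks permutation equivariance; without it MHA is equivariant."""
        cfg = AttentionConfig(d_model=8, n_heads=2, n_layers=1)
        w = _mha_weights(cfg, rng)
        Z = rng.normal(size=(6, 8))
        perm = np.array([3, 1, 5, 0, 4, 2])
        with_rope = multi_head_attention(Z, cfg, w, use_rope=True)
        with_rope_p = multi_head_attention(Z[perm], cfg, w, use_rope=True)
        assert not np.allclose(with_rope[perm], with_rope_p, atol=1e-6)
        no_rope = multi_head_attention(Z, cfg, w, use_rope=False)
        no_rope_p = multi_head_attention(Z[perm], cfg, w, use_rope=False)
        assert np.allclose(no_rope[perm], no_rope_p, atol=1e-10)

    def test_indivisible_width_rejected(self):
        with pytest.raises(ValueError):
            AttentionConfig(d_model=10, n_heads=3, n_layers=1)


class TestEncoder:
    def test_zero_layers_is_identity(self, rng):
        cfg = AttentionConfig(d_model=4, n_heads=1, n_layers=0)
        X = rng.normal(size=(3, 4))
        assert np.allclose(encoder_forward(X, cfg, {"layers": []}), X)

    def test_zero_weights_residual_identity(self, rng):
        cfg = AttentionConfig(d_model=4, n_heads=2, n_layers=2)
        w = init_encoder_weights(cfg, rng)
        for lw in w["layers"]:
            for k, v in lw.items():
                if k == "heads":
                    lw[k] = [np.zeros_like(h) for h in v]
                elif k.endswith("_g"):
                    lw[k] = np.ones_like(v)  # LN gain irrelevant once W = 0
                else:
                    lw[k] = np.zeros_like(v)
        X = rng.normal(size=(5, 4))
        assert np.allclose(encoder_forward(X, cfg, w), X)

    def test_matches_straight_line_oracle(self):
        rng = np.random.default_rng(3)
        cfg = AttentionConfig(d_model=4, n_heads=2, n_layers=1, mlp_hidden=6)
        w = init_encoder_weights(cfg, rng)
        X = rng.normal(size=(3, 4))
        got = encoder_forward(X, cfg, w)
        want = encoder_oracle(X, cfg, w)
        assert np.allclose(got, want, atol=1e-6)

    def test_rope_injected_at_every_layer(self, rng):
        """Disabling rotation in the second of two layers changes outputs."""
        cfg = AttentionConfig(d_model=4, n_heads=2, n_layers=2)
        w = init_encoder_weights(cfg, rng)
        X = rng.normal(size=(5, 4))
        full = encoder_forward(X, cfg, w, use_rope=True)
        cfg1 = AttentionConfig(d_model=4, n_heads=2, n_layers=1)
        mid = encoder_forward(X, cfg1, {"layers": w["layers"][:1]}, use_rope=True)
        hybrid = encoder_forward(mid, cfg1, {"layers": w["layers"][1:]},
                                 use_rope=False)
        assert not np.allclose(full, hybrid, atol=1e-6)

    def test_odd_head_width_rejected(self):
        with pytest.raises(ValueError, match="even"):
            AttentionConfig(d_model=6, n_heads=2, n_layers=1)


class TestActivations:
    def test_mish_known_values(self):
        # mish(0) = 0; mish(x) -> x for large x
        assert mish(np.array(0.0)) == 0.0
        assert np.isclose(mish(np.array(30.0)), 30.0, atol=1e-6)

    def test_layer_norm_standardizes(self, rng):
        x = rng.normal(3, 10, size=(4, 16))
        out = layer_norm(x, np.ones(16), np.zeros(16))
        assert np.allclose(out.mean(-1), 0, atol=1e-7)
        assert np.allclose(out.std(-1), 1, atol=1e-3)
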
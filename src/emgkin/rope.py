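"""Rotary-position-embedding attention mathematics.

Rotary position embedding (RoPE) encodes position by rotating each
consecutive coordinate pair (2i, 2i+1) of a query or key at sequence
position m through the angle m * theta_i, with theta_i = base^(-2i/d).
Because a rotation is orthogonal, row norms are preserved, and the dot
product between a rotated query at position m and a rotated key at
position n depends only on the offset m - n — attention logits become a
function of relative position.  Position information is injected into Q
and K of every attention layer; values never receive it.

Everything here is written against ``autograd.numpy`` so the same code
serves both direct (numpy) evaluation and gradient-based training.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

__all__ = [
    "AttentionConfig",
    "rope_rotate",
    "scaled_dot_attention",
    "attention_weights",
    "multi_head_attention",
    "encoder_forward",
    "mish",
    "layer_norm",
    "init_encoder_weights",
]

LN_EPS = 1e-5


@dataclass
class AttentionConfig:
    """Shape hyperparameters of the encoder stack."""

    d_model: int
    n_heads: int
    n_layers: int
    rope_base: float = 10000.0
    mlp_hidden: int | None = None  # default 4 * d_model

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )
        if self.d_head % 2 != 0:
            raise ValueError(
                f"d_head={self.d_head} must be even (RoPE rotates coordinate pairs)"
            )
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")
        if self.mlp_hidden is None:
            self.mlp_hidden = 4 * self.d_model

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads


def mish(x):
    """Mish activation x * tanh(softplus(x))."""
    # softplus with overflow guard; autograd-safe
    sp = anp.where(x > 20, x, anp.log1p(anp.exp(anp.minimum(x, 20.0))))
    return x * anp.tanh(sp)


def layer_norm(x, gain, bias, eps: float = LN_EPS):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return gain * (x - mu) / anp.sqrt(var + eps) + bias


def _rope_angles(positions, d_head: int, base: float):
    inv_freq = base ** (-anp.arange(0, d_head, 2) / d_head)  # theta_i
    return anp.asarray(positions)[..., None] * inv_freq[None, :]  # [T, d/2]


def rope_rotate(vectors, positions, rope_base: float = 10000.0):
    """Rotate coordinate pairs of ``vectors`` [..., T, d] by position-scaled angles.

    Pair (2i, 2i+1) at position m turns through m * base^(-2i/d); an
    orthogonal map, so every row keeps its Euclidean norm.
    """
    d = vectors.shape[-1]
    if d % 2 != 0:
        raise ValueError(f"head width {d} must be even for RoPE")
    ang = _rope_angles(positions, d, rope_base)
    cos, sin = anp.cos(ang), anp.sin(ang)
    x1 = vectors[..., 0::2]
    x2 = vectors[..., 1::2]
    r1 = x1 * cos - x2 * sin
    r2 = x1 * sin + x2 * cos
    # interleave back to [..., d]
    return anp.reshape(anp.stack([r1, r2], axis=-1), vectors.shape)


def _softmax(logits):
    m = anp.max(logits, axis=-1, keepdims=True)
    e = anp.exp(logits - m)
    return e / anp.sum(e, axis=-1, keepdims=True)


def attention_weights(Q, K):
    """Row-stochastic attention matrix softmax(Q K^T / sqrt(d_h))."""
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError(f"Q width {Q.shape[-1]} != K width {K.shape[-1]}")
    d_h = Q.shape[-1]
    return _softmax(anp.matmul(Q, anp.swapaxes(K, -1, -2)) / anp.sqrt(float(d_h)))


def scaled_dot_attention(Q, K, V):
    """softmax(Q K^T / sqrt(d_h)) V — bidirectional, no causal mask."""
    if K.shape[-2] != V.shape[-2]:
        raise ValueError(
            f"K has {K.shape[-2]} rows but V has {V.shape[-2]}"
        )
    return anp.matmul(attention_weights(Q, K), V)


def multi_head_attention(Z, config: AttentionConfig, weights, positions=None,
                         use_rope: bool = True):
    """H parallel attention heads, concatenated and projected by W_MSA.

    ``weights``: {"heads": [W_qkv per head, each [d_model, 3*d_head]],
    "w_msa": [d_model, d_model]}.  RoPE (when on) acts on each head's Q and
    K only; V carries no positional information.
    """
    T = Z.shape[-2]
    if positions is None:
        positions = np.arange(T)
    outs = []
    for Wqkv in weights["heads"]:
        qkv = anp.matmul(Z, Wqkv)  # [..., T, 3*d_head]
        d_h = config.d_head
        Q = qkv[..., :d_h]
        K = qkv[..., d_h:2 * d_h]
        V = qkv[..., 2 * d_h:]
        if use_rope:
            Q = rope_rotate(Q, positions, config.rope_base)
            K = rope_rotate(K, positions, config.rope_base)
        outs.append(scaled_dot_attention(Q, K, V))
    concat = anp.concatenate(outs, axis=-1)
    return anp.matmul(concat, weights["w_msa"])


def encoder_forward(X_p, config: AttentionConfig, weights, positions=None,
                    use_rope: bool = True):
    """Pre-norm residual encoder stack over a projected input X_p.

    Per layer: Z' = MSA(LayerNorm(Z)) + Z; Z_out = MLP(LayerNorm(Z')) + Z',
    with a linear -> Mish -> linear MLP.  RoPE marks Q/K inside every
    layer's attention, so L = 0 returns the input unchanged.
    """
    Z = X_p
    for i, lw in enumerate(weights["layers"]):
        h = layer_norm(Z, lw["ln1_g"], lw["ln1_b"])
        Z = multi_head_attention(h, config, lw, positions, use_rope=use_rope) + Z
        h = layer_norm(Z, lw["ln2_g"], lw["ln2_b"])
        h = anp.matmul(mish(anp.matmul(h, lw["mlp_w1"]) + lw["mlp_b1"]), lw["mlp_w2"]) + lw["mlp_b2"]
        Z = h + Z
        probe = Z if isinstance(Z, np.ndarray) else getattr(Z, "_value", None)
        if probe is not None and not np.all(np.isfinite(probe)):
            raise FloatingPointError(f"non-finite activations after encoder layer {i}")
    return Z


def init_encoder_weights(config: AttentionConfig, rng: np.random.Generator) -> dict:
    """Scaled-Gaussian initial weights for the encoder stack."""
    d, H, dh = config.d_model, config.n_heads, config.d_head
    hid = config.mlp_hidden
    layers = []
    for _ in range(config.n_layers):
        layers.append({
            "heads": [rng.normal(0, d ** -0.5, size=(d, 3 * dh)) for _ in range(H)],
            "w_msa": rng.normal(0, d ** -0.5, size=(d, d)),
            "ln1_g": np.ones(d), "ln1_b": np.zeros(d),
            "ln2_g": np.ones(d), "ln2_b": np.zeros(d),
            "mlp_w1": rng.normal(0, d ** -0.5, size=(d, hid)),
            "mlp_b1": np.zeros(hid),
            "mlp_w2": rng.normal(0, hid ** -0.5, size=(hid, d)),
            "mlp_b2": np.zeros(d),
        })
    return {"layers": layers}
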
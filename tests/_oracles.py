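"""Independent straight-line oracles used by several test modules.

Deliberately loop-based and unvectorized so they share no code path
with the package implementation they check.
"""

import numpy as np


def rotate_oracle(vec: np.ndarray, position: int, base: float = 10000.0) -> np.ndarray:
    """Rotary embedding via an explicit 2x2 rotation-matrix loop."""
    d = vec.shape[-1]
    out = np.empty_like(vec, dtype=float)
    for i in range(d // 2):
        theta = base ** (-2 * i / d)
        ang = position * theta
        R = np.array([[np.cos(ang), -np.sin(ang)],
                      [np.sin(ang), np.cos(ang)]])
        out[2 * i:2 * i + 2] = R @ vec[2 * i:2 * i + 2]
    return out


def attention_oracle(Q, K, V):
    """Double-loop softmax attention."""
    T, d = Q.shape
    out = np.zeros_like(V, dtype=float)
    for i in range(T):
        logits = np.array([Q[i] @ K[j] / np.sqrt(d) for j in range(K.shape[0])])
        w = np.exp(logits - logits.max())
        w = w / w.sum()
        for j in range(K.shape[0]):
            out[i] += w[j] * V[j]
    return out


def encoder_oracle(X, cfg, w):
    """Loop-based pre-norm encoder reimplementation (single layer)."""

    def ln(row, g, b):
        mu = row.mean()
        var = ((row - mu) ** 2).mean()
        return g * (row - mu) / np.sqrt(var + 1e-5) + b

    def mish_ref(x):
        return x * np.tanh(np.log1p(np.exp(x)))

    Z = X.copy()
    lw = w["layers"][0]
    T = Z.shape[0]
    h = np.stack([ln(Z[t], lw["ln1_g"], lw["ln1_b"]) for t in range(T)])
    heads = []
    for Wqkv in lw["heads"]:
        qkv = h @ Wqkv
        dh = cfg.d_head
        Q = np.stack([rotate_oracle(qkv[t, :dh], t, cfg.rope_base)
                      for t in range(T)])
        K = np.stack([rotate_oracle(qkv[t, dh:2 * dh], t, cfg.rope_base)
                      for t in range(T)])
        heads.append(attention_oracle(Q, K, qkv[:, 2 * dh:]))
    Zp = np.hstack(heads) @ lw["w_msa"] + Z
    h2 = np.stack([ln(Zp[t], lw["ln2_g"], lw["ln2_b"]) for t in range(T)])
    return mish_ref(h2 @ lw["mlp_w1"] + lw["mlp_b1"]) @ lw["mlp_w2"] + lw["mlp_b2"] + Zp
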
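"""The five regressor families and the supervised training loop.

All families map a normalized feature sequence [batch, seq_len, 12] to
joint-angle estimates [batch, seq_len, 10] and share a uniform tail —
a penultimate fully-connected layer (Mish) producing a feature vector
per window, followed by a linear head.  The shared tail makes the
penultimate-feature handle (used by the adversarial calibration), the
fine-tuning freeze set, and the metrics code family-agnostic.

Families
--------
roformer
    1-D conv front layer, then a pre-norm transformer encoder whose
    attention rotates Q/K by rotary position embedding in every layer.
transformer_abs_pe
    Identical encoder with absolute (sinusoidal or learnable) position
    embedding added to the input instead of RoPE — the comparison
    surface for position-embedding ablations.
lstm
    Five stacked LSTM layers, hidden width 32.
tcn
    Five dilated causal convolution layers with residual blocks.
cnn_attention
    Three parallel convolutions (kernels 3/5/7), average pooling, three
    stacked multi-head self-attention modules of three heads each.

Training is plain Adam on mean-squared error with the learning rate
halved at a scheduled epoch.  Gradients come from ``autograd``; there
is no GPU path.
"""

from __future__ import annotations

import copy
import io
import json
from dataclasses import dataclass, field, asdict

import autograd.numpy as anp
import numpy as np
from autograd import grad, value_and_grad
from autograd.misc import flatten

from .rope import (
    AttentionConfig,
    encoder_forward,
    init_encoder_weights,
    mish,
)

__all__ = [
    "RegressorSpec",
    "TrainConfig",
    "Regressor",
    "TrainedRegressor",
    "build_regressor",
    "train_regressor",
    "make_sequences",
    "desk_spec",
    "paper_spec",
    "save_checkpoint",
    "load_checkpoint",
]

FAMILIES = ("roformer", "lstm", "tcn", "transformer_abs_pe", "cnn_attention")


@dataclass
class RegressorSpec:
    """Architecture description for one regressor family."""

    family: str = "roformer"
    position_embedding: str = "rope"  # {rope, sinusoidal, learnable, none}
    n_channels: int = 12
    n_outputs: int = 10
    d_feat: int = 32  # width of the penultimate FC layer
    # encoder families
    d_model: int = 40
    n_heads: int = 5
    n_layers: int = 2
    rope_base: float = 10000.0
    mlp_hidden: int | None = None
    # conv front layer (encoder families)
    conv_kernel: int = 3
    conv_stride: int = 1
    # lstm
    lstm_hidden: int = 32
    lstm_layers: int = 5
    # tcn
    tcn_channels: tuple = (32, 64, 64, 32, 10)
    tcn_kernel: int = 3
    # cnn_attention
    cnn_kernels: tuple = (3, 5, 7)
    cnn_channels: int = 16
    cnn_attn_layers: int = 3
    cnn_attn_heads: int = 3
    pool_width: int = 2
    max_seq_len: int = 512  # learnable-PE table size

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_outputs <= 0 or self.n_channels <= 0:
            raise ValueError("n_channels and n_outputs must be positive")
        expected_pe = {
            "roformer": ("rope",),
            "transformer_abs_pe": ("sinusoidal", "learnable"),
            "lstm": ("none",),
            "tcn": ("none",),
            "cnn_attention": ("sinusoidal", "none"),
        }[self.family]
        if self.position_embedding not in expected_pe:
            raise ValueError(
                f"family {self.family!r} supports position_embedding {expected_pe}, "
                f"got {self.position_embedding!r}"
            )
        if self.family in ("roformer", "transformer_abs_pe"):
            if self.d_model % self.n_heads != 0:
                raise ValueError(
                    f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
                )
            if (self.d_model // self.n_heads) % 2 != 0 and self.family == "roformer":
                raise ValueError("RoPE needs an even head width")
        if self.family == "cnn_attention":
            attn_width = self.cnn_channels * len(self.cnn_kernels)
            if attn_width % self.cnn_attn_heads != 0:
                raise ValueError(
                    f"cnn attention width {attn_width} not divisible by "
                    f"{self.cnn_attn_heads} heads"
                )

    def attention_config(self) -> AttentionConfig:
        if self.family == "cnn_attention":
            return AttentionConfig(
                d_model=self.cnn_channels * len(self.cnn_kernels),
                n_heads=self.cnn_attn_heads, n_layers=self.cnn_attn_layers,
                rope_base=self.rope_base, mlp_hidden=self.mlp_hidden,
            )
        return AttentionConfig(
            d_model=self.d_model, n_heads=self.n_heads, n_layers=self.n_layers,
            rope_base=self.rope_base, mlp_hidden=self.mlp_hidden,
        )


@dataclass
class TrainConfig:
    """Supervised training schedule (Adam on MSE)."""

    batch_size: int = 64
    epochs: int = 400
    lr_init: float = 1e-4
    lr_halve_epoch: int = 200
    seq_len: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_init <= 0:
            raise ValueError("lr_init must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def lr_at(self, epoch: int) -> float:
        return self.lr_init / 2.0 if epoch >= self.lr_halve_epoch else self.lr_init


# ---------------------------------------------------------------------------
# shared building blocks


def _conv1d_same(x, w, b, stride: int = 1):
    """Same-padded 1-D convolution over [B, T, C_in] with kernel [k, C_in, C_out]."""
    k = w.shape[0]
    left, right = (k - 1) // 2, k // 2
    pad = [(0, 0)] * (x.ndim - 2) + [(left, right), (0, 0)]
    xp = anp.pad(x, pad)
    T = x.shape[-2]
    out = sum(anp.matmul(xp[..., j:j + T, :], w[j]) for j in range(k))
    if stride > 1:
        out = out[..., ::stride, :]
    return out + b


def _conv1d_causal(x, w, b, dilation: int = 1):
    """Left-padded dilated causal convolution: output t sees inputs <= t."""
    k = w.shape[0]
    pad = [(0, 0)] * (x.ndim - 2) + [(dilation * (k - 1), 0), (0, 0)]
    xp = anp.pad(x, pad)
    T = x.shape[-2]
    return sum(anp.matmul(xp[..., j * dilation:j * dilation + T, :], w[j])
               for j in range(k)) + b


def _sinusoidal_pe(T: int, d: int) -> np.ndarray:
    pos = np.arange(T)[:, None]
    i = np.arange(d // 2)[None, :]
    ang = pos / (10000.0 ** (2 * i / d))
    pe = np.zeros((T, d))
    pe[:, 0::2] = np.sin(ang)
    pe[:, 1::2] = np.cos(ang[:, : d - d // 2])
    return pe


def _relu(x):
    return anp.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# family forward passes (functions of a params dict; autograd-traceable)


def _encoder_features(spec: RegressorSpec, params, X, use_rope: bool):
    h = _conv1d_same(X, params["conv_w"], params["conv_b"], spec.conv_stride)
    T = h.shape[-2]
    if spec.position_embedding == "sinusoidal":
        h = h + _sinusoidal_pe(T, spec.d_model)
    elif spec.position_embedding == "learnable":
        h = h + params["pos_emb"][:T]
    Z = encoder_forward(h, spec.attention_config(), params["enc"], use_rope=use_rope)
    return mish(anp.matmul(Z, params["feat_w"]) + params["feat_b"])


def _lstm_features(spec: RegressorSpec, params, X):
    h = X
    for lw in params["lstm"]:
        B, T = h.shape[0], h.shape[1]
        hidden = spec.lstm_hidden
        ht = anp.zeros((B, hidden))
        ct = anp.zeros((B, hidden))
        outs = []
        for t in range(T):
            z = anp.matmul(h[:, t, :], lw["wx"]) + anp.matmul(ht, lw["wh"]) + lw["b"]
            i_g = _sigmoid(z[:, :hidden])
            f_g = _sigmoid(z[:, hidden:2 * hidden] + 1.0)  # forget-gate bias offset
            g_g = anp.tanh(z[:, 2 * hidden:3 * hidden])
            o_g = _sigmoid(z[:, 3 * hidden:])
            ct = f_g * ct + i_g * g_g
            ht = o_g * anp.tanh(ct)
            outs.append(ht)
        h = anp.stack(outs, axis=1)
    return mish(anp.matmul(h, params["feat_w"]) + params["feat_b"])


def _sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def _tcn_features(spec: RegressorSpec, params, X):
    h = X
    for i, lw in enumerate(params["tcn"]):
        dilation = 2 ** i
        y = _relu(_conv1d_causal(h, lw["w"], lw["b"], dilation))
        res = anp.matmul(h, lw["proj"]) if "proj" in lw else h
        h = y + res
    return mish(anp.matmul(h, params["feat_w"]) + params["feat_b"])


def _cnn_attention_features(spec: RegressorSpec, params, X):
    branches = [
        _conv1d_same(X, bw["w"], bw["b"]) for bw in params["branches"]
    ]
    h = _relu(anp.concatenate(branches, axis=-1))
    T = h.shape[-2]
    # average pooling (width 2) shortens the sequence to broaden the
    # receptive field; pad an odd tail by repeating the last step
    p = spec.pool_width
    rem = (-T) % p
    if rem:
        h = anp.concatenate([h, anp.repeat(h[..., -1:, :], rem, axis=-2)], axis=-2)
    Tp = h.shape[-2] // p
    h = anp.mean(anp.reshape(h, h.shape[:-2] + (Tp, p, h.shape[-1])), axis=-2)
    d_attn = spec.cnn_channels * len(spec.cnn_kernels)
    if spec.position_embedding == "sinusoidal":
        h = h + _sinusoidal_pe(Tp, d_attn)
    Z = encoder_forward(h, spec.attention_config(), params["enc"], use_rope=False)
    # nearest-neighbour upsample back to the input length to honour the
    # shared sequence-preserving forward contract
    Z = anp.repeat(Z, p, axis=-2)[..., :T, :]
    return mish(anp.matmul(Z, params["feat_w"]) + params["feat_b"])


def family_features(spec: RegressorSpec, params, X):
    """Penultimate-layer feature sequence [B, T, d_feat] for any family."""
    if X.shape[-1] != spec.n_channels:
        raise ValueError(
            f"expected {spec.n_channels} input channels, got {X.shape[-1]}"
        )
    if spec.family == "roformer":
        return _encoder_features(spec, params, X, use_rope=True)
    if spec.family == "transformer_abs_pe":
        return _encoder_features(spec, params, X, use_rope=False)
    if spec.family == "lstm":
        return _lstm_features(spec, params, X)
    if spec.family == "tcn":
        return _tcn_features(spec, params, X)
    return _cnn_attention_features(spec, params, X)


def family_forward(spec: RegressorSpec, params, X):
    """Joint-angle estimates [B, T, n_outputs]."""
    feats = family_features(spec, params, X)
    return anp.matmul(feats, params["head_w"]) + params["head_b"]


# ---------------------------------------------------------------------------
# parameter initialization


def init_params(spec: RegressorSpec, rng: np.random.Generator) -> dict:
    C, d_feat = spec.n_channels, spec.d_feat
    params: dict = {}
    if spec.family in ("roformer", "transformer_abs_pe"):
        d = spec.d_model
        params["conv_w"] = rng.normal(0, (spec.conv_kernel * C) ** -0.5,
                                      size=(spec.conv_kernel, C, d))
        params["conv_b"] = np.zeros(d)
        if spec.position_embedding == "learnable":
            params["pos_emb"] = rng.normal(0, 0.02, size=(spec.max_seq_len, d))
        params["enc"] = init_encoder_weights(spec.attention_config(), rng)
        feat_in = d
    elif spec.family == "lstm":
        layers = []
        in_w = C
        for _ in range(spec.lstm_layers):
            h = spec.lstm_hidden
            layers.append({
                "wx": rng.normal(0, in_w ** -0.5, size=(in_w, 4 * h)),
                "wh": rng.normal(0, h ** -0.5, size=(h, 4 * h)),
                "b": np.zeros(4 * h),
            })
            in_w = h
        params["lstm"] = layers
        feat_in = spec.lstm_hidden
    elif spec.family == "tcn":
        layers = []
        in_w = C
        for ch in spec.tcn_channels:
            lw = {
                "w": rng.normal(0, (spec.tcn_kernel * in_w) ** -0.5,
                                size=(spec.tcn_kernel, in_w, ch)),
                "b": np.zeros(ch),
            }
            if in_w != ch:
                lw["proj"] = rng.normal(0, in_w ** -0.5, size=(in_w, ch))
            layers.append(lw)
            in_w = ch
        params["tcn"] = layers
        feat_in = spec.tcn_channels[-1]
    else:  # cnn_attention
        params["branches"] = [
            {"w": rng.normal(0, (k * C) ** -0.5, size=(k, C, spec.cnn_channels)),
             "b": np.zeros(spec.cnn_channels)}
            for k in spec.cnn_kernels
        ]
        params["enc"] = init_encoder_weights(spec.attention_config(), rng)
        feat_in = spec.cnn_channels * len(spec.cnn_kernels)
    params["feat_w"] = rng.normal(0, feat_in ** -0.5, size=(feat_in, d_feat))
    params["feat_b"] = np.zeros(d_feat)
    params["head_w"] = rng.normal(0, d_feat ** -0.5, size=(d_feat, spec.n_outputs))
    params["head_b"] = np.zeros(spec.n_outputs)
    return params


def n_parameters(params) -> int:
    flat, _ = flatten(params)
    return int(flat.size)


# ---------------------------------------------------------------------------
# regressor objects


class Regressor:
    """An (initially untrained) regressor: spec + parameter pytree."""

    def __init__(self, spec: RegressorSpec, params: dict, seed: int | None = None):
        self.spec = spec
        self.params = params
        self.seed = seed

    @property
    def n_params(self) -> int:
        return n_parameters(self.params)

    def _as_batch(self, features: np.ndarray) -> tuple[np.ndarray, bool]:
        features = np.asarray(features, dtype=float)
        if features.ndim == 2:
            return features[None], True
        return features, False

    def forward(self, features: np.ndarray) -> np.ndarray:
        """Joint-angle estimates in degrees; a 2-D input is one sequence."""
        X, squeeze = self._as_batch(features)
        out = np.asarray(family_forward(self.spec, self.params, X))
        # trained models regress in label-standardized space internally
        mean = getattr(self, "label_mean", None)
        if mean is not None:
            out = out * self.label_std + mean
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite regressor output")
        return out[0] if squeeze else out

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Forward pass at the model's trained context length.

        A 2-D feature matrix is split into consecutive chunks of the
        training sequence length so inference sees the same attention
        context the model was optimized for.
        """
        features = np.asarray(features, dtype=float)
        cfg = getattr(self, "config", None)
        if features.ndim != 2 or cfg is None:
            return self.forward(features)
        L = cfg.seq_len
        return np.vstack([self.forward(features[s:s + L])
                          for s in range(0, features.shape[0], L)])

    def penultimate(self, features: np.ndarray) -> np.ndarray:
        """Output of the penultimate fully-connected layer, per window."""
        X, squeeze = self._as_batch(features)
        out = np.asarray(family_features(self.spec, self.params, X))
        return out[0] if squeeze else out

    def copy(self) -> "Regressor":
        dup = copy.deepcopy(self)
        return dup


class TrainedRegressor(Regressor):
    """A trained regressor with its loss history and normalization digest."""

    def __init__(self, spec, params, history, config: TrainConfig,
                 norm_hash: str | None = None, seed: int | None = None,
                 label_mean: np.ndarray | None = None,
                 label_std: np.ndarray | None = None):
        super().__init__(spec, params, seed)
        self.history = list(history)
        self.config = config
        self.norm_hash = norm_hash
        self.label_mean = label_mean
        self.label_std = label_std


def build_regressor(spec: RegressorSpec, seed: int = 0) -> Regressor:
    """Deterministically initialize an untrained regressor."""
    rng = np.random.default_rng(seed)
    return Regressor(spec, init_params(spec, rng), seed=seed)


# ---------------------------------------------------------------------------
# training


def make_sequences(series_list, seq_len: int):
    """Chunk FeatureSeries into non-overlapping [N, seq_len, ...] tensors."""
    xs, ys = [], []
    for fs in series_list:
        n = fs.n_windows // seq_len
        for i in range(n):
            sl = slice(i * seq_len, (i + 1) * seq_len)
            xs.append(fs.features[sl])
            ys.append(fs.labels[sl])
    if not xs:
        raise ValueError(
            f"no training sequences: series too short for seq_len={seq_len}"
        )
    return np.stack(xs), np.stack(ys)


class Adam:
    """Plain Adam over a flattened parameter vector."""

    def __init__(self, n: int, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def step(self, x: np.ndarray, g: np.ndarray, lr: float) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * g
        self.v = self.beta2 * self.v + (1 - self.beta2) * g * g
        mhat = self.m / (1 - self.beta1 ** self.t)
        vhat = self.v / (1 - self.beta2 ** self.t)
        return x - lr * mhat / (np.sqrt(vhat) + self.eps)


def _fit(spec, params, X, Y, config: TrainConfig, loss_of_forward=None):
    """Adam/MSE loop shared by supervised training and FT calibration."""

    def loss(p, xb, yb):
        pred = family_forward(spec, p, xb)
        return anp.mean((pred - yb) ** 2)

    loss_fn = loss if loss_of_forward is None else loss_of_forward
    vg_fn = value_and_grad(loss_fn)
    flat, unflatten = flatten(params)
    opt = Adam(flat.size)
    rng = np.random.default_rng(config.seed)
    history = []
    n = X.shape[0]
    for epoch in range(config.epochs):
        lr = config.lr_at(epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = X[idx], Y[idx]
            p = unflatten(flat)
            l_val, g_tree = vg_fn(p, xb, yb)
            l_val = float(l_val)
            if not np.isfinite(l_val):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {l_val} "
                    f"(history so far: {history[-3:]})"
                )
            g, _ = flatten(g_tree)
            flat = opt.step(flat, g, lr)
            losses.append(l_val)
        history.append(float(np.mean(losses)))
    return unflatten(flat), history


def train_regressor(regressor: Regressor, train_data, config: TrainConfig,
                    norm_hash: str | None = None) -> TrainedRegressor:
    """Supervised MSE training over chunked sequences of the training series."""
    series = list(train_data)
    if not series:
        raise ValueError("empty training set")
    X, Y = make_sequences(series, config.seq_len)
    if norm_hash is None:
        hashes = {fs.norm_hash for fs in series if fs.norm_hash is not None}
        norm_hash = hashes.pop() if len(hashes) == 1 else None
    # regress in label-standardized space (Adam steps are O(lr) per weight,
    # so degree-scale targets would need impractically many updates)
    label_mean = Y.mean(axis=(0, 1))
    label_std = np.maximum(Y.std(axis=(0, 1)), 1e-6)
    Ys = (Y - label_mean) / label_std
    params, history = _fit(regressor.spec, copy.deepcopy(regressor.params),
                           X, Ys, config)
    return TrainedRegressor(regressor.spec, params, history, config,
                            norm_hash=norm_hash, seed=regressor.seed,
                            label_mean=label_mean, label_std=label_std)


# ---------------------------------------------------------------------------
# profiles and checkpoints


def desk_spec(family: str = "roformer", **overrides) -> RegressorSpec:
    """Small configuration that trains in seconds on one CPU."""
    base = dict(
        roformer=dict(d_model=40, n_heads=5, n_layers=2, d_feat=32, mlp_hidden=80),
        transformer_abs_pe=dict(d_model=40, n_heads=5, n_layers=2, d_feat=32,
                                mlp_hidden=80, position_embedding="sinusoidal"),
        lstm=dict(lstm_hidden=24, lstm_layers=2, d_feat=32, position_embedding="none"),
        tcn=dict(tcn_channels=(16, 24, 16), d_feat=32, position_embedding="none"),
        cnn_attention=dict(cnn_channels=8, cnn_attn_layers=2, cnn_attn_heads=3,
                           d_feat=32, mlp_hidden=48, position_embedding="sinusoidal"),
    )[family]
    base.update(overrides)
    return RegressorSpec(family=family, **base)


def paper_spec(family: str = "roformer", **overrides) -> RegressorSpec:
    """Full-size configuration (2 encoder layers, 5 heads, etc.)."""
    base = dict(
        roformer=dict(d_model=40, n_heads=5, n_layers=2),
        transformer_abs_pe=dict(d_model=40, n_heads=5, n_layers=2,
                                position_embedding="sinusoidal"),
        lstm=dict(lstm_hidden=32, lstm_layers=5, position_embedding="none"),
        tcn=dict(tcn_channels=(32, 64, 64, 32, 10), position_embedding="none"),
        cnn_attention=dict(cnn_channels=16, cnn_attn_layers=3, cnn_attn_heads=3,
                           position_embedding="sinusoidal"),
    )[family]
    base.update(overrides)
    return RegressorSpec(family=family, **base)


def save_checkpoint(model: TrainedRegressor, path) -> None:
    """Single-file weight archive with an embedded JSON spec block."""
    flat, _ = flatten(model.params)
    spec_block = json.dumps({
        "spec": asdict(model.spec),
        "seed": model.seed,
        "norm_hash": model.norm_hash,
        "history": model.history,
        "config": asdict(model.config),
        "label_mean": None if model.label_mean is None else np.asarray(model.label_mean).tolist(),
        "label_std": None if model.label_std is None else np.asarray(model.label_std).tolist(),
    })
    np.savez(path, flat=flat, spec_json=np.frombuffer(spec_block.encode(), dtype=np.uint8))


def load_checkpoint(path, expect_channels: int | None = None) -> TrainedRegressor:
    with np.load(path) as z:
        flat = z["flat"]
        meta = json.loads(bytes(z["spec_json"]).decode())
    sd = meta["spec"]
    for key in ("tcn_channels", "cnn_kernels"):
        sd[key] = tuple(sd[key])
    spec = RegressorSpec(**sd)
    if expect_channels is not None and spec.n_channels != expect_channels:
        raise ValueError(
            f"checkpoint expects {spec.n_channels} channels, data has {expect_channels}"
        )
    template = init_params(spec, np.random.default_rng(0))
    _, unflatten = flatten(template)
    cfg = TrainConfig(**meta["config"])
    lm = meta.get("label_mean")
    ls = meta.get("label_std")
    return TrainedRegressor(spec, unflatten(flat), meta["history"], cfg,
                            norm_hash=meta["norm_hash"], seed=meta["seed"],
                            label_mean=None if lm is None else np.asarray(lm),
                            label_std=None if ls is None else np.asarray(ls))
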
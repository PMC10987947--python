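"""Calibrating a cross-subject model to a new subject.

Two routes are provided:

* **Fine-tuning (FT)** — copy the cross-subject network, freeze every
  parameter except the final head, and minimize MSE on the new
  subject's training trials.

* **Adversarial transfer learning (ATL)** — a GAN-style scheme with
  three players.  The frozen multi-subject network (Multi-s-net)
  produces source features F_s; a trainable copy (New-t-net) produces
  target features F_t from the new subject; a small MLP domain
  discriminator (DD) estimates the probability a feature vector came
  from the source domain.  Per batch the DD takes one step on

      L_DD = mean( -log DD(F_s) - log(1 - DD(F_t)) ),

  then New-t-net takes one step on

      L_mapping + L_subject
        = mean( -log DD(F_t) )  +  w * mean_b sum_j (N_net(x) - x_hat)^2,

  so New-t-net is pushed both to fool the discriminator (aligning the
  target feature distribution with the source's) and to fit the new
  subject's labels.  Features are the output of the penultimate
  fully-connected layer of the regressor; the total objective is the
  exact sum L_total = L_DD + L_mapping + L_subject.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.misc import flatten

from .models import (
    Adam,
    Regressor,
    TrainedRegressor,
    family_features,
    make_sequences,
)
from .rope import mish

__all__ = [
    "DomainDiscriminator",
    "AtlConfig",
    "AtlState",
    "dd_loss",
    "mapping_loss",
    "subject_loss",
    "total_loss",
    "atl_calibrate",
    "ft_calibrate",
    "weight_digest",
]

PROB_EPS = 1e-7


def _clamp(p):
    return anp.clip(p, PROB_EPS, 1.0 - PROB_EPS)


def dd_loss(p_source, p_target) -> float:
    """Discriminator objective: mean(-log p_s - log(1 - p_t)) over the batch."""
    p_s = anp.atleast_1d(p_source)
    p_t = anp.atleast_1d(p_target)
    if p_s.size == 0 or p_t.size == 0:
        raise ValueError("empty probability batch")
    return anp.mean(-anp.log(_clamp(p_s))) + anp.mean(-anp.log(1.0 - _clamp(p_t)))


def mapping_loss(p_target) -> float:
    """Generator-side confusion objective: mean(-log p_t)."""
    p_t = anp.atleast_1d(p_target)
    if p_t.size == 0:
        raise ValueError("empty probability batch")
    return anp.mean(-anp.log(_clamp(p_t)))


def subject_loss(pred, labels, w: float) -> float:
    """Reweighted supervised term: w * mean over batch of the summed squared
    error across the N joints."""
    if not hasattr(pred, "shape"):
        pred = anp.array(pred, dtype=float)
    if not hasattr(labels, "shape"):
        labels = anp.array(labels, dtype=float)
    if pred.shape != labels.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {labels.shape}")
    if w < 0:
        raise ValueError("w must be >= 0")
    per_sample = anp.sum((pred - labels) ** 2, axis=-1)
    return w * anp.mean(per_sample)


def total_loss(l_dd, l_mapping, l_subject) -> float:
    """Exact sum of the three calibration terms."""
    for name, v in (("dd", l_dd), ("mapping", l_mapping), ("subject", l_subject)):
        if not np.isfinite(v):
            raise ValueError(f"non-finite {name} loss component: {v}")
    return l_dd + l_mapping + l_subject


# ---------------------------------------------------------------------------
# domain discriminator


class DomainDiscriminator:
    """MLP mapping a penultimate feature vector to P(source domain) in (0, 1)."""

    def __init__(self, in_width: int, hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.in_width = in_width
        self.params = {
            "w1": rng.normal(0, in_width ** -0.5, size=(in_width, hidden)),
            "b1": np.zeros(hidden),
            "w2": rng.normal(0, hidden ** -0.5, size=(hidden, hidden)),
            "b2": np.zeros(hidden),
            "w3": rng.normal(0, hidden ** -0.5, size=(hidden, 1)),
            "b3": np.zeros(1),
        }

    @staticmethod
    def apply(params, feats):
        h = mish(anp.matmul(feats, params["w1"]) + params["b1"])
        h = mish(anp.matmul(h, params["w2"]) + params["b2"])
        logit = anp.matmul(h, params["w3"]) + params["b3"]
        p = 0.5 * (anp.tanh(0.5 * logit) + 1.0)  # sigmoid
        return _clamp(p[..., 0])

    def predict_proba(self, feats: np.ndarray) -> np.ndarray:
        return np.asarray(self.apply(self.params, np.asarray(feats, dtype=float)))


@dataclass
class AtlConfig:
    """Calibration schedule: 50 epochs at lr 1e-3, batch 64, by default."""

    epochs: int = 50
    batch_size: int = 64
    lr: float = 1e-3
    w: float = 1.0  # weight of the supervised subject term
    dd_hidden: int = 64
    dd_steps_per_step: int = 1
    seq_len: int = 150
    seed: int = 0


@dataclass
class AtlState:
    """The three players plus the per-epoch loss log."""

    multi_s_net: TrainedRegressor
    new_t_net: TrainedRegressor
    dd: DomainDiscriminator
    w: float
    log: list = field(default_factory=list)


def weight_digest(model: Regressor) -> str:
    """SHA-256 digest of the flattened parameter vector (frozen-source check)."""
    flat, _ = flatten(model.params)
    return hashlib.sha256(np.ascontiguousarray(flat, dtype=np.float64).tobytes()).hexdigest()


def _window_batches(X, Y, batch_size, rng):
    """Yield seeded window-level batches from sequence tensors [N, L, ...]."""
    flatX = X.reshape(-1, X.shape[-1])
    flatY = Y.reshape(-1, Y.shape[-1])
    n = flatX.shape[0]
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        idx = order[start:start + batch_size]
        yield flatX[idx], flatY[idx]


def atl_calibrate(multi_s_net: TrainedRegressor, target_train, source_pool,
                  config: AtlConfig | None = None) -> TrainedRegressor:
    """Adversarially calibrate a cross-subject model to a new subject.

    Alternates, per batch: (a) a DD step on L_DD with source features from
    the frozen Multi-s-net and target features from New-t-net; (b) a
    New-t-net step on L_mapping + L_subject over target batches.  Returns
    the calibrated New-t-net; Multi-s-net is untouched (bit-checked).
    """
    cfg = config or AtlConfig()
    spec = multi_s_net.spec
    src_digest = weight_digest(multi_s_net)

    Xt, Yt = make_sequences(list(target_train), cfg.seq_len)
    Xs, Ys = make_sequences(list(source_pool), cfg.seq_len)
    # the source network regresses in its own label-standardized space
    if multi_s_net.label_mean is not None:
        Yt = (Yt - multi_s_net.label_mean) / multi_s_net.label_std

    new_t = copy.deepcopy(multi_s_net)
    dd = DomainDiscriminator(spec.d_feat, hidden=cfg.dd_hidden, seed=cfg.seed + 1)

    # sequence-level feature extraction; features are per-window vectors
    def target_feats(p, xb):
        return family_features(spec, p, xb)

    def dd_objective(dd_params, f_s, f_t):
        return dd_loss(DomainDiscriminator.apply(dd_params, f_s),
                       DomainDiscriminator.apply(dd_params, f_t))

    def gen_objective(net_params, dd_params, xb, yb):
        feats = family_features(spec, net_params, xb)
        p_t = DomainDiscriminator.apply(dd_params, feats)
        pred = anp.matmul(feats, net_params["head_w"]) + net_params["head_b"]
        return mapping_loss(p_t) + subject_loss(pred, yb, cfg.w)

    dd_vg = value_and_grad(dd_objective)
    gen_vg = value_and_grad(gen_objective)

    net_flat, net_unflatten = flatten(new_t.params)
    dd_flat, dd_unflatten = flatten(dd.params)
    opt_net = Adam(net_flat.size)
    opt_dd = Adam(dd_flat.size)
    rng = np.random.default_rng(cfg.seed)
    log = []

    n_t = Xt.shape[0]
    n_s = Xs.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_t)
        ep = {"l_dd": [], "l_mapping": [], "l_subject": [], "l_total": [],
              "dd_acc": []}
        for start in range(0, n_t, max(1, cfg.batch_size // cfg.seq_len)):
            t_idx = order[start:start + max(1, cfg.batch_size // cfg.seq_len)]
            xb_t, yb_t = Xt[t_idx], Yt[t_idx]
            s_idx = rng.integers(0, n_s, size=len(t_idx))
            xb_s = Xs[s_idx]

            net_p = net_unflatten(net_flat)
            f_s = np.asarray(family_features(spec, multi_s_net.params, xb_s))
            f_s = f_s.reshape(-1, spec.d_feat)
            f_t = np.asarray(family_features(spec, net_p, xb_t))
            f_t = f_t.reshape(-1, spec.d_feat)

            # (a) discriminator step(s)
            for _ in range(cfg.dd_steps_per_step):
                dd_p = dd_unflatten(dd_flat)
                l_dd, g = dd_vg(dd_p, f_s, f_t)
                l_dd = float(l_dd)
                if not np.isfinite(l_dd):
                    raise FloatingPointError(
                        f"DD loss collapsed to {l_dd} at epoch {epoch}; log: {log[-3:]}"
                    )
                gflat, _ = flatten(g)
                dd_flat = opt_dd.step(dd_flat, gflat, cfg.lr)

            # (b) New-t-net step on mapping + subject terms
            dd_p = dd_unflatten(dd_flat)
            l_gen, g = gen_vg(net_p, dd_p, xb_t, yb_t)
            if not np.isfinite(float(l_gen)):
                raise FloatingPointError(
                    f"New-t-net loss collapsed at epoch {epoch}; log: {log[-3:]}"
                )
            gflat, _ = flatten(g)
            net_flat = opt_net.step(net_flat, gflat, cfg.lr)

            # bookkeeping on fresh values
            net_p = net_unflatten(net_flat)
            f_t2 = np.asarray(family_features(spec, net_p, xb_t)).reshape(-1, spec.d_feat)
            p_s = DomainDiscriminator.apply(dd_unflatten(dd_flat), f_s)
            p_t = DomainDiscriminator.apply(dd_unflatten(dd_flat), f_t2)
            pred = f_t2 @ net_p["head_w"] + net_p["head_b"]
            l_map = float(mapping_loss(p_t))
            l_sub = float(subject_loss(pred, yb_t.reshape(-1, yb_t.shape[-1]), cfg.w))
            l_dd_now = float(dd_loss(p_s, p_t))
            ep["l_dd"].append(l_dd_now)
            ep["l_mapping"].append(l_map)
            ep["l_subject"].append(l_sub)
            ep["l_total"].append(total_loss(l_dd_now, l_map, l_sub))
            acc = 0.5 * (np.mean(np.asarray(p_s) > 0.5) + np.mean(np.asarray(p_t) <= 0.5))
            ep["dd_acc"].append(float(acc))
        log.append({k: float(np.mean(v)) for k, v in ep.items()})

    if weight_digest(multi_s_net) != src_digest:
        raise RuntimeError("Multi-s-net weights changed during ATL calibration")

    cal = TrainedRegressor(spec, net_unflatten(net_flat),
                           multi_s_net.history + [e["l_subject"] for e in log],
                           multi_s_net.config, norm_hash=multi_s_net.norm_hash,
                           seed=multi_s_net.seed,
                           label_mean=multi_s_net.label_mean,
                           label_std=multi_s_net.label_std)
    cal.atl_log = log
    cal.dd = DomainDiscriminator(spec.d_feat, hidden=cfg.dd_hidden, seed=cfg.seed + 1)
    cal.dd.params = dd_unflatten(dd_flat)
    return cal


def ft_calibrate(multi_s_net: TrainedRegressor, target_train,
                 config: AtlConfig | None = None) -> TrainedRegressor:
    """Fine-tune only the final head on the new subject's training trials."""
    cfg = config or AtlConfig()
    spec = multi_s_net.spec
    src_digest = weight_digest(multi_s_net)
    Xt, Yt = make_sequences(list(target_train), cfg.seq_len)
    if multi_s_net.label_mean is not None:
        Yt = (Yt - multi_s_net.label_mean) / multi_s_net.label_std

    frozen = copy.deepcopy(multi_s_net.params)
    head0 = {"head_w": frozen.pop("head_w"), "head_b": frozen.pop("head_b")}

    # precompute frozen-body features once: only the head trains
    feats = np.asarray(family_features(spec, {**frozen, **head0}, Xt))
    F = feats.reshape(-1, spec.d_feat)
    Yf = Yt.reshape(-1, Yt.shape[-1])

    def loss(head, fb, yb):
        pred = anp.matmul(fb, head["head_w"]) + head["head_b"]
        return anp.mean((pred - yb) ** 2)

    vg = value_and_grad(loss)
    flat, unflatten = flatten(head0)
    opt = Adam(flat.size)
    rng = np.random.default_rng(cfg.seed)
    history = []
    n = F.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            head = unflatten(flat)
            l_val, g = vg(head, F[idx], Yf[idx])
            if not np.isfinite(float(l_val)):
                raise FloatingPointError(f"FT loss collapsed at epoch {epoch}")
            gflat, _ = flatten(g)
            flat = opt.step(flat, gflat, cfg.lr)
            losses.append(float(l_val))
        history.append(float(np.mean(losses)))

    if weight_digest(multi_s_net) != src_digest:
        raise RuntimeError("source network changed during FT calibration")

    head = unflatten(flat)
    params = {**copy.deepcopy(frozen), **head}
    return TrainedRegressor(spec, params, multi_s_net.history + history,
                            multi_s_net.config, norm_hash=multi_s_net.norm_hash,
                            seed=multi_s_net.seed,
                            label_mean=multi_s_net.label_mean,
                            label_std=multi_s_net.label_std)
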
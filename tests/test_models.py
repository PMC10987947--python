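"""Regressor construction, forward contracts, and the training loop."""

import numpy as np
import pytest

from autograd.misc import flatten

from emgkin.models import (
    RegressorSpec,
    TrainConfig,
    build_regressor,
    desk_spec,
    load_checkpoint,
    make_sequences,
    save_checkpoint,
    train_regressor,
)
from emgkin.signal_prep import FeatureSeries

TINY = dict(d_model=8, n_heads=2, n_layers=1, d_feat=8, mlp_hidden=16)


def _linear_series(rng, n=400, n_ch=12, n_j=10):
    """Labels are a fixed linear readout of the features."""
    W = rng.normal(size=(n_ch, n_j))
    X = rng.uniform(0.3, 1.0, size=(n, n_ch))
    Y = 40 + 20 * (X @ W)
    return FeatureSeries(X, Y, 100, 50, ("s", "M1", 1))


class TestBuild:
    def test_same_seed_same_weights(self):
        spec = desk_spec("roformer")
        a = build_regressor(spec, seed=5)
        b = build_regressor(spec, seed=5)
        fa, _ = flatten(a.params)
        fb, _ = flatten(b.params)
        assert np.array_equal(fa, fb)

    def test_head_divisibility(self):
        RegressorSpec(family="roformer", d_model=40, n_heads=5)  # accepted
        with pytest.raises(ValueError, match="divisible"):
            RegressorSpec(family="roformer", d_model=42, n_heads=5)

    def test_family_position_embedding_consistency(self):
        with pytest.raises(ValueError, match="position_embedding"):
            RegressorSpec(family="lstm", position_embedding="rope")
        with pytest.raises(ValueError, match="position_embedding"):
            RegressorSpec(family="roformer", position_embedding="sinusoidal")

    def test_parameter_count_hand_total(self):
        # conv(3*2*4 + 4) + heads 2*(4*6) + msa 16 + ln 16 + mlp(32+8+32+4)
        # + feat(16+4) + head(40+10) = 254
        spec = RegressorSpec(family="roformer", n_channels=2, d_model=4,
                             n_heads=2, n_layers=1, mlp_hidden=8, d_feat=4)
        model = build_regressor(spec, 0)
        assert model.n_params == 254

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            RegressorSpec(family="gru")


@pytest.mark.parametrize("family", ["roformer", "lstm", "tcn",
                                    "transformer_abs_pe", "cnn_attention"])
class TestForwardContract:
    def test_shape_and_finiteness(self, family, rng):
        model = build_regressor(desk_spec(family), 0)
        X = rng.uniform(0, 1, size=(2, 20, 12))
        out = model.forward(X)
        assert out.shape == (2, 20, 10)
        assert np.all(np.isfinite(out))

    def test_batch_duplication(self, family, rng):
        model = build_regressor(desk_spec(family), 0)
        X = rng.uniform(0, 1, size=(1, 16, 12))
        single = model.forward(X)
        double = model.forward(np.concatenate([X, X]))
        assert np.allclose(double[0], double[1])
        assert np.allclose(double[0], single[0])

    def test_penultimate_handle_width(self, family, rng):
        spec = desk_spec(family)
        model = build_regressor(spec, 0)
        feats = model.penultimate(rng.uniform(0, 1, size=(14, 12)))
        assert feats.shape == (14, spec.d_feat)

    def test_wrong_channel_count(self, family, rng):
        model = build_regressor(desk_spec(family), 0)
        with pytest.raises(ValueError, match="channels"):
            model.forward(rng.uniform(size=(1, 10, 7)))


class TestPositionSensitivity:
    def test_roformer_output_changes_under_permutation(self, rng):
        model = build_regressor(desk_spec("roformer"), 0)
        X = rng.uniform(0, 1, size=(18, 12))
        perm = rng.permutation(18)
        out = model.forward(X)
        out_p = model.forward(X[perm])
        assert not np.allclose(out[perm], out_p, atol=1e-6)

    def test_pe_variants_share_all_other_parameter_shapes(self):
        """The position-embedding component is the only difference."""
        def shapes(model):
            flat = {}

            def rec(prefix, node):
                if isinstance(node, dict):
                    for k, v in node.items():
                        rec(f"{prefix}.{k}", v)
                elif isinstance(node, list):
                    for i, v in enumerate(node):
                        rec(f"{prefix}[{i}]", v)
                else:
                    flat[prefix] = np.shape(node)
            rec("", model.params)
            return flat

        rope = shapes(build_regressor(desk_spec("roformer"), 0))
        sin = shapes(build_regressor(desk_spec("transformer_abs_pe"), 0))
        learn = shapes(build_regressor(desk_spec(
            "transformer_abs_pe", position_embedding="learnable"), 0))
        assert rope == sin
        assert set(learn) - set(sin) == {".pos_emb"}
        assert {k: v for k, v in learn.items() if k != ".pos_emb"} == sin


class TestTraining:
    def test_loss_decreases_on_attainable_fit(self, rng):
        fs = _linear_series(rng, n=200)
        model = build_regressor(RegressorSpec(family="roformer", **TINY), 0)
        cfg = TrainConfig(batch_size=8, epochs=50, lr_init=1e-3,
                          lr_halve_epoch=25, seq_len=20, seed=0)
        trained = train_regressor(model, [fs], cfg)
        assert len(trained.history) == 50
        assert trained.history[-1] < trained.history[0]

    def test_identical_seeds_identical_weights(self, rng):
        fs = _linear_series(rng, n=120)
        cfg = TrainConfig(batch_size=8, epochs=3, lr_init=1e-3,
                          lr_halve_epoch=2, seq_len=20, seed=4)
        runs = []
        for _ in range(2):
            model = build_regressor(RegressorSpec(family="roformer", **TINY), 4)
            flat, _ = flatten(train_regressor(model, [fs], cfg).params)
            runs.append(flat)
        assert np.array_equal(runs[0], runs[1])

    def test_lr_schedule_halves_exactly(self):
        cfg = TrainConfig(epochs=400, lr_init=1e-4, lr_halve_epoch=200)
        assert cfg.lr_at(199) == 1e-4
        assert cfg.lr_at(200) == 5e-5
        assert cfg.lr_at(399) == 5e-5

    def test_linear_mapping_reaches_high_training_cc(self, rng):
        from emgkin.metrics import pearson_cc
        fs = _linear_series(rng, n=400)
        spec = RegressorSpec(family="roformer", d_model=16, n_heads=2,
                             n_layers=1, d_feat=16, mlp_hidden=32)
        model = build_regressor(spec, 0)
        cfg = TrainConfig(batch_size=8, epochs=400, lr_init=3e-3,
                          lr_halve_epoch=200, seq_len=20, seed=0)
        trained = train_regressor(model, [fs], cfg)
        pred = trained.predict(fs.features)
        ccs = [pearson_cc(fs.labels[:, j], pred[:, j]) for j in range(10)]
        assert np.mean(ccs) > 0.99

    def test_empty_training_set_rejected(self):
        model = build_regressor(RegressorSpec(family="roformer", **TINY), 0)
        with pytest.raises(ValueError, match="empty"):
            train_regressor(model, [], TrainConfig(epochs=1))

    def test_make_sequences_chunking(self, rng):
        fs = _linear_series(rng, n=55)
        X, Y = make_sequences([fs], 20)
        assert X.shape == (2, 20, 12) and Y.shape == (2, 20, 10)


def test_checkpoint_round_trip(tmp_path, rng):
    fs = _linear_series(rng, n=80)
    model = build_regressor(RegressorSpec(family="roformer", **TINY), 0)
    cfg = TrainConfig(batch_size=8, epochs=2, lr_init=1e-3,
                      lr_halve_epoch=1, seq_len=20, seed=0)
    trained = train_regressor(model, [fs], cfg, norm_hash="cafe")
    path = tmp_path / "model.npz"
    save_checkpoint(trained, path)
    back = load_checkpoint(path)
    assert back.spec == trained.spec
    assert back.norm_hash == "cafe"
    X = rng.uniform(size=(1, 20, 12))
    assert np.allclose(back.forward(X), trained.forward(X))
    with pytest.raises(ValueError, match="channels"):
        load_checkpoint(path, expect_channels=7)
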
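"""Canonical desk-scale studies on the synthetic cohort.

These presets fix the study conditions — cohort geometry, training
schedule, calibration schedule — at a scale one CPU handles in minutes,
and are what the bundled reproduction script and the heavier tests run.
Problem sizes: one 3-movement subject (subject-specific recovery), a
3-subject / 2-movement source pool with a held-out subject (domain
shift and transfer), 5-second trials, 100 ms windows at a 50 ms step,
25-window training contexts.
"""

from __future__ import annotations

import numpy as np

from . import signal_prep as sp
from .experiment import build_features, desk_train_config, split_cohort
from .metrics import evaluate_model
from .models import build_regressor, desk_spec, train_regressor
from .synthetic import SyntheticCohortSpec, generate_cohort, generate_held_out
from .transfer import AtlConfig, atl_calibrate, ft_calibrate, weight_digest

__all__ = [
    "subject_specific_recovery",
    "shift_degradation",
    "transfer_comparison",
    "null_shift_control",
    "SUBJECT_STUDY_COHORT",
    "TRANSFER_STUDY_COHORT",
    "TRANSFER_STUDY_SHIFT",
    "SHIFT_LEVELS",
]

TRIAL_S = 5.0
SEQ_LEN = 25
TRANSFER_STUDY_SHIFT = 6.0
SHIFT_LEVELS = (0.0, 3.0, 6.0)
DESK_ATL = dict(epochs=50, lr=1e-4, seq_len=SEQ_LEN)

SUBJECT_STUDY_COHORT = dict(n_subjects=1, n_movements=3,
                            trial_duration_s=TRIAL_S, shift_magnitude=0.0)
TRANSFER_STUDY_COHORT = dict(n_subjects=3, n_movements=2,
                             trial_duration_s=TRIAL_S)


def subject_specific_recovery(seed: int, epochs: int = 150) -> dict:
    """Train a desk RoFormer on 4 trials of one synthetic subject and
    score it on the held-out 2 trials."""
    cohort = generate_cohort(SyntheticCohortSpec(**SUBJECT_STUDY_COHORT), seed)
    train_recs, test_recs = split_cohort(cohort.recordings, seed)
    train_fs, test_fs, norm = build_features(train_recs, test_recs)
    model = build_regressor(desk_spec("roformer"), seed)
    cfg = desk_train_config("subject_specific", seed=seed, seq_len=SEQ_LEN,
                            epochs=epochs)
    trained = train_regressor(model, train_fs, cfg, norm_hash=norm.digest())
    rep = evaluate_model(trained, test_fs)
    return {"cc": rep.ave_cc, "nrmse": rep.ave_nrmse, "r2": rep.ave_r2,
            "n_windows": sum(f.n_windows for f in test_fs)}


def _train_source(seed: int, epochs: int = 60):
    """Cross-subject source model on the pooled training trials.

    The source pool is independent of the held-out subject's shift, so
    one model per seed serves every shift level.
    """
    spec = SyntheticCohortSpec(shift_magnitude=0.0, **TRANSFER_STUDY_COHORT)
    cohort = generate_cohort(spec, seed)
    src_train, _ = split_cohort(cohort.recordings, seed)
    src_fs, _, norm = build_features(src_train, [])
    model = build_regressor(desk_spec("roformer"), seed)
    cfg = desk_train_config("cross_subject", seed=seed, seq_len=SEQ_LEN,
                            epochs=epochs)
    source = train_regressor(model, src_fs, cfg, norm_hash=norm.digest())
    return source, src_fs, norm


def _target_sets(seed: int, shift: float, norm):
    spec = SyntheticCohortSpec(shift_magnitude=shift, **TRANSFER_STUDY_COHORT)
    _, held_out_recs = generate_held_out(spec, seed)
    tgt_train, tgt_test = split_cohort(held_out_recs, seed)
    tgt_train_fs = [sp.prepare_features(r, norm) for r in tgt_train]
    tgt_test_fs = [sp.prepare_features(r, norm) for r in tgt_test]
    return tgt_train_fs, tgt_test_fs


def _source_and_target(seed: int, shift: float, epochs: int = 60):
    source, src_fs, norm = _train_source(seed, epochs)
    tgt_train_fs, tgt_test_fs = _target_sets(seed, shift, norm)
    return source, src_fs, tgt_train_fs, tgt_test_fs


def shift_degradation(seed: int, shifts=SHIFT_LEVELS, epochs: int = 60) -> list:
    """noTL test CC on the held-out subject at increasing shift levels."""
    source, _, norm = _train_source(seed, epochs)
    out = []
    for shift in shifts:
        _, tgt_test_fs = _target_sets(seed, shift, norm)
        rep = evaluate_model(source, tgt_test_fs)
        out.append({"shift": shift, "cc": rep.ave_cc, "r2": rep.ave_r2})
    return out


def transfer_comparison(seed: int, shift: float = TRANSFER_STUDY_SHIFT,
                        epochs: int = 60) -> dict:
    """noTL / FT / ATL comparison on one shifted held-out subject."""
    source, src_fs, tgt_train_fs, tgt_test_fs = _source_and_target(
        seed, shift, epochs)
    acfg = AtlConfig(seed=seed, **DESK_ATL)
    digest_before = weight_digest(source)
    ft = ft_calibrate(source, tgt_train_fs, acfg)
    atl = atl_calibrate(source, tgt_train_fs, src_fs, acfg)
    result = {
        "noTL": evaluate_model(source, tgt_test_fs).ave_cc,
        "FT": evaluate_model(ft, tgt_test_fs).ave_cc,
        "ATL": evaluate_model(atl, tgt_test_fs).ave_cc,
        "source_frozen": weight_digest(source) == digest_before,
        "dd_acc_last10": float(np.mean([e["dd_acc"] for e in atl.atl_log[-10:]])),
    }
    return result


def null_shift_control(seed: int, epochs: int = 60) -> dict:
    """ATL when the held-out subject sits at the cohort mean (no shift):
    DD should end confused and the calibrated CC should match noTL."""
    source, src_fs, tgt_train_fs, tgt_test_fs = _source_and_target(
        seed, 0.0, epochs)
    acfg = AtlConfig(seed=seed, **DESK_ATL)
    digest_before = weight_digest(source)
    atl = atl_calibrate(source, tgt_train_fs, src_fs, acfg)
    return {
        "noTL_cc": evaluate_model(source, tgt_test_fs).ave_cc,
        "ATL_cc": evaluate_model(atl, tgt_test_fs).ave_cc,
        "dd_acc_last10": float(np.mean([e["dd_acc"] for e in atl.atl_log[-10:]])),
        "source_frozen": weight_digest(source) == digest_before,
    }
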
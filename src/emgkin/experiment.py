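"""Experiment orchestration: the three evaluation conditions.

* subject-specific — one model per subject, trained on 4 of its 6
  trials per movement and tested on the other 2;
* cross-subject — one model on the pooled training trials of all
  subjects, tested per subject;
* transfer — train on all subjects except a held-out one, then compare
  noTL (no calibration), FT (head-only fine-tuning) and ATL
  (adversarial calibration) on the held-out subject's test trials.

Normalization statistics are always fitted on the training split in
scope (one subject, the pool, or the 9-subject source pool) and frozen
for test and target data.  Every access to a recording is logged so
tests can assert that no test trial leaks into training or calibration.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import signal_prep as sp
from .metrics import aggregate_reports, evaluate_model
from .models import (
    RegressorSpec,
    TrainConfig,
    build_regressor,
    desk_spec,
    paper_spec,
    train_regressor,
)
from .synthetic import SyntheticCohortSpec, generate_cohort
from .transfer import AtlConfig, atl_calibrate, ft_calibrate

__all__ = [
    "ExperimentConfig",
    "AccessLog",
    "split_cohort",
    "build_features",
    "run_subject_specific",
    "run_cross_subject",
    "run_transfer",
    "desk_train_config",
]


class AccessLog:
    """Record of which (phase, subject, movement, trial) was touched."""

    def __init__(self) -> None:
        self.entries: list[tuple] = []

    def record(self, phase: str, rec) -> None:
        self.entries.append((phase, rec.subject_id, rec.movement_id, rec.trial_id))

    def trials(self, phase: str, subject_id: str) -> set:
        return {(m, t) for p, s, m, t in self.entries
                if p == phase and s == subject_id}


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    condition: str = "subject_specific"  # {subject_specific, cross_subject, transfer}
    families: tuple = ("roformer",)
    normalization: str = "mu_law"
    mu: float = sp.DEFAULT_MU
    approaches: tuple = ("noTL", "FT", "ATL")
    profile: str = "desk"  # {desk, paper}
    seed: int = 0
    window_ms: float = sp.DEFAULT_WINDOW_MS
    step_ms: float = sp.DEFAULT_STEP_MS
    cohort: SyntheticCohortSpec = field(default_factory=SyntheticCohortSpec)
    out_dir: str | None = None
    train_config: TrainConfig | None = None  # overrides the profile schedule

    def __post_init__(self) -> None:
        if self.condition not in ("subject_specific", "cross_subject", "transfer"):
            raise ValueError(f"unknown condition {self.condition!r}")
        unknown = set(self.approaches) - {"noTL", "FT", "ATL"}
        if unknown:
            raise ValueError(f"unknown transfer approaches {sorted(unknown)}")


def _subject_seed(seed: int, subject_id: str) -> int:
    return (seed * 1000003 + zlib.crc32(subject_id.encode())) % (2**31)


def split_cohort(recordings, seed: int):
    """4/2 train/test split per subject; one partition shared by all of a
    subject's movements."""
    by_subject_movement: dict = {}
    for rec in recordings:
        by_subject_movement.setdefault((rec.subject_id, rec.movement_id), []).append(rec)
    train, test = [], []
    for (sid, mid), recs in sorted(by_subject_movement.items()):
        tr_ids, te_ids = sp.split_trials([r.trial_id for r in recs],
                                         seed=_subject_seed(seed, sid))
        for r in recs:
            (train if r.trial_id in tr_ids else test).append(r)
    return train, test


def build_features(train_recs, test_recs, method: str = "mu_law",
                   mu: float = sp.DEFAULT_MU,
                   window_ms: float = sp.DEFAULT_WINDOW_MS,
                   step_ms: float = sp.DEFAULT_STEP_MS,
                   log: AccessLog | None = None, phase: str = "train"):
    """Fit normalization on the training recordings, featurize both splits."""
    spec = sp.fit_normalization(
        [sp.raw_rms(r, window_ms, step_ms) for r in train_recs], method, mu)
    train_fs, test_fs = [], []
    for r in train_recs:
        if log is not None:
            log.record(phase, r)
        train_fs.append(sp.prepare_features(r, spec, window_ms, step_ms))
    for r in test_recs:
        test_fs.append(sp.prepare_features(r, spec, window_ms, step_ms))
    return train_fs, test_fs, spec


def desk_train_config(condition: str, seed: int = 0, seq_len: int = 25,
                      epochs: int = 100, lr: float = 1e-3,
                      batch_size: int = 8) -> TrainConfig:
    """Desk-scale schedule: short contexts, small batches, minutes on CPU.

    The compressed epoch budget is compensated by a higher learning rate
    than the full-scale schedule; the halving step moves to mid-run.
    """
    return TrainConfig(batch_size=batch_size, epochs=epochs, lr_init=lr,
                       lr_halve_epoch=max(1, epochs // 2), seq_len=seq_len,
                       seed=seed)


def paper_train_config(condition: str, seed: int = 0) -> TrainConfig:
    lr = 3e-4 if condition == "subject_specific" else 1e-4
    return TrainConfig(batch_size=64, epochs=400, lr_init=lr,
                       lr_halve_epoch=200, seq_len=150, seed=seed)


def _spec_for(family: str, profile: str) -> RegressorSpec:
    return desk_spec(family) if profile == "desk" else paper_spec(family)


def _train_cfg(config: ExperimentConfig) -> TrainConfig:
    if config.train_config is not None:
        return config.train_config
    if config.profile == "desk":
        return desk_train_config(config.condition, seed=config.seed)
    return paper_train_config(config.condition, seed=config.seed)


def run_subject_specific(config: ExperimentConfig, recordings=None,
                         log: AccessLog | None = None):
    """One model per subject per family, evaluated on held-out trials."""
    log = log or AccessLog()
    if recordings is None:
        recordings = generate_cohort(config.cohort, config.seed).recordings
    subjects = sorted({r.subject_id for r in recordings})
    reports = []
    for sid in subjects:
        recs = [r for r in recordings if r.subject_id == sid]
        train_recs, test_recs = split_cohort(recs, config.seed)
        train_fs, test_fs, norm = build_features(
            train_recs, test_recs, config.normalization, config.mu,
            config.window_ms, config.step_ms, log, f"train:{sid}")
        for family in config.families:
            model = build_regressor(_spec_for(family, config.profile), config.seed)
            trained = train_regressor(model, train_fs, _train_cfg(config),
                                      norm_hash=norm.digest())
            rep = evaluate_model(trained, test_fs, {
                "subject": sid, "family": family,
                "normalization": config.normalization,
                "condition": "subject_specific",
            })
            reports.append(rep)
    _maybe_write(config, reports, "subject_specific")
    return reports


def run_cross_subject(config: ExperimentConfig, recordings=None,
                      log: AccessLog | None = None):
    """One pooled model per family, evaluated per subject."""
    log = log or AccessLog()
    if recordings is None:
        recordings = generate_cohort(config.cohort, config.seed).recordings
    subjects = sorted({r.subject_id for r in recordings})
    if len(subjects) < 2:
        raise ValueError("cross-subject condition needs >= 2 subjects")
    train_recs, test_recs = split_cohort(recordings, config.seed)
    train_fs, test_fs, norm = build_features(
        train_recs, test_recs, config.normalization, config.mu,
        config.window_ms, config.step_ms, log, "train:pool")
    reports = []
    for family in config.families:
        model = build_regressor(_spec_for(family, config.profile), config.seed)
        trained = train_regressor(model, train_fs, _train_cfg(config),
                                  norm_hash=norm.digest())
        for sid in subjects:
            sub_test = [fs for fs in test_fs if fs.provenance[0] == sid]
            rep = evaluate_model(trained, sub_test, {
                "subject": sid, "family": family,
                "normalization": config.normalization,
                "condition": "cross_subject",
            })
            reports.append(rep)
    _maybe_write(config, reports, "cross_subject")
    return reports


def run_transfer(config: ExperimentConfig, source_recordings=None,
                 target_recordings=None, log: AccessLog | None = None,
                 atl_config: AtlConfig | None = None):
    """noTL / FT / ATL comparison on a held-out subject.

    The source pool must not contain the held-out subject; the frozen
    source model and its normalization statistics are shared by all
    three approaches, which are evaluated on identical test windows.
    """
    log = log or AccessLog()
    if source_recordings is None or target_recordings is None:
        cohort = generate_cohort(config.cohort, config.seed)
        source_recordings = cohort.recordings
        target_recordings = cohort.held_out_recordings
    target_ids = {r.subject_id for r in target_recordings}
    if len(target_ids) != 1:
        raise ValueError(f"expected one held-out subject, got {sorted(target_ids)}")
    target_id = target_ids.pop()
    if any(r.subject_id == target_id for r in source_recordings):
        raise ValueError(f"held-out subject {target_id!r} found in the source pool")

    src_train, _ = split_cohort(source_recordings, config.seed)
    tgt_train, tgt_test = split_cohort(target_recordings, config.seed)

    src_fs, _, norm = build_features(
        src_train, [], config.normalization, config.mu,
        config.window_ms, config.step_ms, log, "train:source")
    # held-out subject features use the frozen source normalization
    tgt_test_fs = [sp.prepare_features(r, norm, config.window_ms, config.step_ms)
                   for r in tgt_test]

    cfg_train = _train_cfg(config)
    if atl_config is not None:
        acfg = atl_config
    elif config.profile == "desk":
        # the desk profile calibrates at a lower rate: with tiny target sets
        # the full-scale 1e-3 steps destroy the pretrained solution
        acfg = AtlConfig(seq_len=cfg_train.seq_len, seed=config.seed, lr=1e-4)
    else:
        acfg = AtlConfig(seq_len=cfg_train.seq_len, seed=config.seed)
    results: dict = {}
    for family in config.families:
        model = build_regressor(_spec_for(family, config.profile), config.seed)
        source_model = train_regressor(model, src_fs, cfg_train,
                                       norm_hash=norm.digest())
        fam_reports = {}
        for approach in config.approaches:
            if approach == "noTL":
                calibrated = source_model
            else:
                tgt_train_fs = []
                for r in tgt_train:
                    log.record(f"calibrate:{approach}", r)
                    tgt_train_fs.append(
                        sp.prepare_features(r, norm, config.window_ms, config.step_ms))
                if approach == "FT":
                    calibrated = ft_calibrate(source_model, tgt_train_fs, acfg)
                else:
                    calibrated = atl_calibrate(source_model, tgt_train_fs,
                                               src_fs, acfg)
            rep = evaluate_model(calibrated, tgt_test_fs, {
                "subject": target_id, "family": family,
                "normalization": config.normalization,
                "condition": "transfer", "approach": approach,
            })
            fam_reports[approach] = rep
        results[family] = fam_reports

    table = pd.DataFrame([
        {"approach": ap, "family": fam, "ave_cc": rep.ave_cc,
         "ave_nrmse": rep.ave_nrmse, "ave_r2": rep.ave_r2}
        for fam, reps in results.items() for ap, rep in reps.items()
    ])
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "transfer_table.csv", index=False)
    results["table"] = table
    results["access_log"] = log
    results["test_windows_digest"] = _windows_digest(tgt_test_fs)
    return results


def _windows_digest(series) -> str:
    import hashlib
    h = hashlib.sha256()
    for fs in series:
        h.update(np.ascontiguousarray(fs.features).tobytes())
        h.update(np.ascontiguousarray(fs.labels).tobytes())
    return h.hexdigest()[:16]


def _maybe_write(config: ExperimentConfig, reports, name: str) -> None:
    if not config.out_dir:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    detail = pd.concat([r.to_frame() for r in reports], ignore_index=True)
    detail.to_csv(out / f"{name}_per_joint.csv", index=False)
    summary = aggregate_reports(reports)
    summary.to_csv(out / f"{name}_summary.csv", index=False)
    cfg = asdict(config)
    cfg["cohort"] = asdict(config.cohort)
    (out / f"{name}_config.json").write_text(json.dumps(cfg, indent=2, default=str))
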
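"""Seeded synthetic sEMG/kinematics cohorts with controllable domain shift.

The generator emulates the statistical structure the regression method
assumes: smooth joint-angle trajectories drive non-negative muscle
activations, which amplitude-modulate band-limited noise carriers mixed
onto 12 electrode channels.  Subjects differ in per-channel gain, in
their muscle-to-electrode mixing matrix, and in a mild activation
nonlinearity — the amplitude idiosyncrasies that make cross-subject
transfer hard for real surface EMG.  A held-out subject is perturbed
from the cohort mean by a tunable ``shift_magnitude``; zero shift makes
the held-out subject's spec exactly the cohort mean.

Everything is a pure function of the seeds in the specs, so cohorts are
exactly regenerable from a manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .signal_prep import SubjectRecording

__all__ = [
    "SyntheticSubjectSpec",
    "SyntheticCohortSpec",
    "generate_trial",
    "generate_subject_spec",
    "generate_cohort",
    "generate_held_out",
    "movement_targets",
    "movement_timing",
    "cohort_readout",
]

N_CHANNELS = 12
N_MUSCLES = 6
N_JOINTS = 10
REST_ANGLE = 5.0  # degrees
ANGLE_MAX = 90.0
CARRIER_BAND = (20.0, 450.0)  # Hz, standard surface-EMG energy band


@dataclass
class SyntheticSubjectSpec:
    """Per-subject idiosyncrasies of the angle -> EMG-envelope mapping."""

    subject_id: str
    mixing: np.ndarray  # [12, n_muscles], non-negative synergy weights
    gain: np.ndarray  # [12], per-channel positive scalar
    noise_sd: np.ndarray  # [12], additive sensor noise
    nonlinearity_exponent: np.ndarray  # [n_muscles], near 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        self.nonlinearity_exponent = np.asarray(self.nonlinearity_exponent, dtype=float)
        if np.any(self.mixing < 0):
            raise ValueError("mixing weights must be non-negative")
        if np.any(self.mixing.sum(axis=1) <= 0):
            raise ValueError("every channel needs at least one non-zero mixing weight")
        if np.any(self.gain <= 0):
            raise ValueError("gain must be positive")
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticCohortSpec:
    """Cohort geometry: 10 subjects x 6 movements x 6 trials by default."""

    n_subjects: int = 10
    n_movements: int = 6
    n_trials: int = 6
    trial_duration_s: float = 4.0
    fs_emg: float = 2000.0
    fs_angles: float = 20.0
    n_joints: int = N_JOINTS
    n_muscles: int = N_MUSCLES
    shift_magnitude: float = 1.0
    subject_sd: float = 0.12  # within-cohort spec spread
    noise_sd: float = 0.02  # sensor-noise scale

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_movements, self.n_trials) <= 0:
            raise ValueError("cohort counts must be positive")
        if self.shift_magnitude < 0:
            raise ValueError("shift_magnitude must be >= 0")


def _seed_of(*parts: int) -> np.random.Generator:
    ss = np.random.SeedSequence(list(parts))
    return np.random.default_rng(ss)


def movement_targets(cohort: SyntheticCohortSpec, master_seed: int) -> np.ndarray:
    """Target posture per movement [n_movements, n_joints], degrees.

    Shared across subjects: a movement is the same grasp for everyone.
    """
    rng = _seed_of(master_seed, 7001)
    return rng.uniform(25.0, ANGLE_MAX, size=(cohort.n_movements, cohort.n_joints))


def cohort_readout(cohort: SyntheticCohortSpec, master_seed: int):
    """Cohort-level angle/velocity -> muscle-activation read-out weights."""
    rng = _seed_of(master_seed, 7002)
    w_ang = rng.uniform(0.0, 1.0, size=(cohort.n_muscles, cohort.n_joints))
    w_ang *= rng.random(w_ang.shape) < 0.6  # sparse synergies
    w_ang[w_ang.sum(axis=1) == 0, rng.integers(0, cohort.n_joints)] = 0.5
    # every joint is actuated: guarantee one solid readout weight per joint,
    # otherwise a weakly-read joint is unrecoverable from any electrode
    weak = w_ang.max(axis=0) < 0.3
    w_ang[rng.integers(0, cohort.n_muscles, size=int(weak.sum())), np.flatnonzero(weak)] = \
        rng.uniform(0.5, 1.0, size=int(weak.sum()))
    w_vel = 0.3 * rng.uniform(0.0, 1.0, size=(cohort.n_muscles, cohort.n_joints))
    return w_ang, w_vel


def _mean_subject_spec(cohort: SyntheticCohortSpec, master_seed: int) -> dict:
    rng = _seed_of(master_seed, 7003)
    mixing = rng.uniform(0.2, 1.0, size=(N_CHANNELS, cohort.n_muscles))
    mixing *= rng.random(mixing.shape) < 0.7
    # guarantee every channel reads at least one muscle
    dead = mixing.sum(axis=1) == 0
    mixing[dead, rng.integers(0, cohort.n_muscles, size=int(dead.sum()))] = 0.6
    return {
        "mixing": mixing,
        "gain": np.ones(N_CHANNELS),
        "noise_sd": np.full(N_CHANNELS, cohort.noise_sd),
        "exponent": np.ones(cohort.n_muscles),
    }


def generate_subject_spec(cohort: SyntheticCohortSpec, master_seed: int,
                          subject_index: int, magnitude: float | None = None,
                          subject_id: str | None = None) -> SyntheticSubjectSpec:
    """Draw one subject's spec around the cohort mean.

    ``magnitude`` scales the perturbation; 0 returns the mean spec exactly.
    """
    mean = _mean_subject_spec(cohort, master_seed)
    mag = cohort.subject_sd if magnitude is None else magnitude
    rng = _seed_of(master_seed, 7100, subject_index)
    mixing = mean["mixing"] * np.exp(rng.normal(0, mag, size=mean["mixing"].shape))
    gain = mean["gain"] * np.exp(rng.normal(0, 2.0 * mag, size=N_CHANNELS))
    exponent = mean["exponent"] + rng.normal(0, 0.4 * mag, size=cohort.n_muscles)
    exponent = np.clip(exponent, 0.5, 1.6)
    return SyntheticSubjectSpec(
        subject_id=subject_id or f"S{subject_index + 1:02d}",
        mixing=mixing, gain=gain, noise_sd=mean["noise_sd"].copy(),
        nonlinearity_exponent=exponent,
        seed=int(_seed_of(master_seed, 7200, subject_index).integers(0, 2**31)),
    )


def _sigmoid(t: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-t))


def movement_timing(cohort: SyntheticCohortSpec, master_seed: int):
    """Per-movement, per-joint transition timing (shared across subjects).

    Joints engage and release at staggered times within a grasp, so the
    ten angle trajectories of one movement are correlated but not
    collinear — decoding them requires resolving individual muscles.
    """
    rng = _seed_of(master_seed, 7004)
    shape = (cohort.n_movements, cohort.n_joints)
    rise = rng.uniform(0.15, 0.45, size=shape)  # fraction of trial duration
    fall = rng.uniform(0.55, 0.85, size=shape)
    steep = rng.uniform(5.0, 12.0, size=shape)  # 1/s
    return rise, fall, steep


def _angle_trajectory(cohort: SyntheticCohortSpec, target: np.ndarray,
                      timing: tuple, rng: np.random.Generator) -> np.ndarray:
    """Rest -> target -> rest per joint, sigmoidal, with trial-level jitter."""
    m = int(round(cohort.trial_duration_s * cohort.fs_angles))
    t = np.arange(m) / cohort.fs_angles
    dur = cohort.trial_duration_s
    rise, fall, steep = timing
    jit = rng.uniform(-0.04, 0.04) + rng.uniform(-0.02, 0.02, size=rise.shape)
    rise_c = (rise + jit) * dur
    fall_c = (fall + jit) * dur
    env = (_sigmoid(steep[None, :] * (t[:, None] - rise_c[None, :]))
           - _sigmoid(steep[None, :] * (t[:, None] - fall_c[None, :])))
    env = np.clip(env, 0.0, 1.0)
    return REST_ANGLE + env * (target[None, :] - REST_ANGLE)


def _bandpass_carrier(n: int, fs: float, rng: np.random.Generator,
                      n_channels: int) -> np.ndarray:
    lo, hi = CARRIER_BAND
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    white = rng.standard_normal((n, n_channels))
    carrier = sps.sosfiltfilt(sos, white, axis=0)
    # unit RMS per channel so the envelope sets the amplitude scale
    rms = np.sqrt(np.mean(carrier**2, axis=0))
    return carrier / rms


def generate_trial(subject_spec: SyntheticSubjectSpec, movement_id: str,
                   trial_id: int, cohort: SyntheticCohortSpec,
                   master_seed: int = 0) -> SubjectRecording:
    """Simulate one trial: angles at fs_angles, sEMG at fs_emg.

    Deterministic in (subject seed, movement, trial): repeated calls
    return bit-identical recordings.
    """
    mv_index = int(str(movement_id).lstrip("M")) - 1
    targets = movement_targets(cohort, master_seed)
    if not 0 <= mv_index < cohort.n_movements:
        raise ValueError(f"movement {movement_id!r} outside cohort grid")
    w_ang, w_vel = cohort_readout(cohort, master_seed)
    rise, fall, steep = movement_timing(cohort, master_seed)
    timing = (rise[mv_index], fall[mv_index], steep[mv_index])
    rng = _seed_of(subject_spec.seed, mv_index, trial_id)

    angles = _angle_trajectory(cohort, targets[mv_index], timing, rng)  # [m, J]

    # normalized kinematic drive
    ang_n = (angles - REST_ANGLE) / (ANGLE_MAX - REST_ANGLE)
    vel = np.gradient(angles, 1.0 / cohort.fs_angles, axis=0)
    vel_n = np.abs(vel) / (ANGLE_MAX - REST_ANGLE)

    act = ang_n @ w_ang.T + vel_n @ w_vel.T  # [m, n_muscles], >= 0
    act = np.clip(act, 0.0, None)
    act = act ** subject_spec.nonlinearity_exponent[None, :]

    envelope = act @ subject_spec.mixing.T * subject_spec.gain[None, :]  # [m, 12]

    n = int(round(cohort.trial_duration_s * cohort.fs_emg))
    t_emg = np.arange(n) / cohort.fs_emg
    t_ang = np.arange(angles.shape[0]) / cohort.fs_angles
    env_up = np.empty((n, N_CHANNELS))
    for c in range(N_CHANNELS):
        env_up[:, c] = np.interp(t_emg, t_ang, envelope[:, c])

    carrier = _bandpass_carrier(n, cohort.fs_emg, rng, N_CHANNELS)
    emg = carrier * env_up + subject_spec.noise_sd[None, :] * rng.standard_normal((n, N_CHANNELS))

    return SubjectRecording(
        subject_id=subject_spec.subject_id, movement_id=f"M{mv_index + 1}",
        trial_id=int(trial_id), emg=emg, angles=angles,
        fs_emg=cohort.fs_emg, fs_angles=cohort.fs_angles,
    )


@dataclass
class SyntheticCohort:
    """A generated cohort: recordings plus the specs that regenerate them."""

    cohort_spec: SyntheticCohortSpec
    master_seed: int
    subject_specs: list
    held_out_spec: SyntheticSubjectSpec
    recordings: list  # SubjectRecording, cohort subjects
    held_out_recordings: list

    def manifest(self) -> dict:
        def spec_dict(s: SyntheticSubjectSpec) -> dict:
            d = asdict(s)
            return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in d.items()}
        return {
            "cohort_spec": asdict(self.cohort_spec),
            "master_seed": self.master_seed,
            "subjects": [spec_dict(s) for s in self.subject_specs],
            "held_out": spec_dict(self.held_out_spec),
        }

    def save_manifest(self, path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2))


def _subject_grid(spec, cohort_spec, master_seed):
    return [
        generate_trial(spec, f"M{m + 1}", tr, cohort_spec, master_seed)
        for m in range(cohort_spec.n_movements)
        for tr in range(1, cohort_spec.n_trials + 1)
    ]


def generate_held_out(cohort_spec: SyntheticCohortSpec, master_seed: int = 0,
                      held_out_id: str = "NEW"):
    """The held-out subject's spec and full trial grid, without the cohort.

    At shift 0 the spec is exactly the cohort mean (identical domains).
    """
    if cohort_spec.shift_magnitude == 0:
        mean = _mean_subject_spec(cohort_spec, master_seed)
        held_out = SyntheticSubjectSpec(
            subject_id=held_out_id, mixing=mean["mixing"], gain=mean["gain"],
            noise_sd=mean["noise_sd"], nonlinearity_exponent=mean["exponent"],
            seed=int(_seed_of(master_seed, 7200, cohort_spec.n_subjects + 1000)
                     .integers(0, 2**31)),
        )
    else:
        held_out = generate_subject_spec(
            cohort_spec, master_seed, cohort_spec.n_subjects + 1000,
            magnitude=cohort_spec.subject_sd * cohort_spec.shift_magnitude,
            subject_id=held_out_id,
        )
    return held_out, _subject_grid(held_out, cohort_spec, master_seed)


def generate_cohort(cohort_spec: SyntheticCohortSpec, master_seed: int = 0,
                    held_out_id: str = "NEW") -> SyntheticCohort:
    """Generate the full subject x movement x trial grid plus a held-out
    subject perturbed from the cohort mean by ``shift_magnitude``."""
    subject_specs = [
        generate_subject_spec(cohort_spec, master_seed, i)
        for i in range(cohort_spec.n_subjects)
    ]
    held_out, held_out_recs = generate_held_out(cohort_spec, master_seed,
                                                held_out_id)
    recordings = [rec for s in subject_specs
                  for rec in _subject_grid(s, cohort_spec, master_seed)]
    return SyntheticCohort(
        cohort_spec=cohort_spec, master_seed=master_seed,
        subject_specs=subject_specs, held_out_spec=held_out,
        recordings=recordings, held_out_recordings=held_out_recs,
    )
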
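"""Raw recording -> normalized feature/label series.

Turns paired sEMG / data-glove recordings into windowed RMS features with
time-aligned joint-angle labels: sliding-window RMS, mu-law (or Z-score)
normalization, label resampling to window centres, and the per-movement
4/2 trial split.

The mu-law compander is the odd logarithmic map

    F(x) = sign(x) * ln(1 + mu*|x|) / ln(1 + mu),   |x| <= 1,

which amplifies small amplitudes — where most of the informative sEMG
energy lives — while pinning the endpoints F(0)=0, F(+-1)=+-1.  Raw RMS
is brought into [0, 1] beforehand by a per-channel prescale fitted on
training data only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecording",
    "FeatureSeries",
    "NormalizationSpec",
    "compute_rms_windows",
    "mu_law_normalize",
    "mu_law_inverse",
    "zscore_normalize",
    "resample_labels",
    "split_trials",
    "fit_normalization",
    "apply_normalization",
    "prepare_features",
    "save_feature_series",
    "load_feature_series",
]

DEFAULT_MU = float(2**20)
DEFAULT_WINDOW_MS = 100.0
DEFAULT_STEP_MS = 50.0  # the recording sheet's literal 0.5 ms step remains selectable


@dataclass
class SubjectRecording:
    """One subject/movement/trial of raw sEMG plus glove joint angles."""

    subject_id: str
    movement_id: str
    trial_id: int
    emg: np.ndarray  # [n_samples, n_channels]
    angles: np.ndarray  # [m_samples, n_joints], degrees
    fs_emg: float = 2000.0
    fs_angles: float = 20.0

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.emg.ndim != 2 or self.angles.ndim != 2:
            raise ValueError("emg and angles must be 2-D [samples, channels]")
        if not np.all(np.isfinite(self.emg)):
            raise ValueError("emg contains non-finite values")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles contains non-finite values")
        if self.fs_emg <= 0 or self.fs_angles <= 0:
            raise ValueError("sampling rates must be positive")
        # durations must agree to within one label period
        dur_emg = self.emg.shape[0] / self.fs_emg
        dur_ang = self.angles.shape[0] / self.fs_angles
        if abs(dur_emg - dur_ang) > 1.0 / self.fs_angles + 1e-9:
            raise ValueError(
                f"emg duration {dur_emg:.3f}s and angle duration {dur_ang:.3f}s "
                "disagree by more than one label period"
            )

    @property
    def n_channels(self) -> int:
        return self.emg.shape[1]

    @property
    def n_joints(self) -> int:
        return self.angles.shape[1]


@dataclass
class FeatureSeries:
    """Windowed, normalized RMS features with one label row per window."""

    features: np.ndarray  # [n_windows, n_channels]
    labels: np.ndarray  # [n_windows, n_joints], degrees
    window_ms: float
    step_ms: float
    provenance: tuple  # (subject_id, movement_id, trial_id)
    norm_hash: str | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"features ({self.features.shape[0]} windows) and labels "
                f"({self.labels.shape[0]} windows) are misaligned"
            )
        if not np.all(np.isfinite(self.features)) or not np.all(np.isfinite(self.labels)):
            raise ValueError("FeatureSeries contains non-finite values")

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]


@dataclass
class NormalizationSpec:
    """Frozen normalization statistics, fitted on training data only."""

    method: str = "mu_law"  # {"mu_law", "zscore"}
    mu: float = DEFAULT_MU
    prescale: np.ndarray | None = None  # per-channel divisor into [0, 1]
    zscore_mean: np.ndarray | None = None
    zscore_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.method not in ("mu_law", "zscore"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if self.mu <= 0:
            raise ValueError("mu must be positive")

    def digest(self) -> str:
        """Stable hash identifying the frozen statistics."""
        h = hashlib.sha256()
        h.update(self.method.encode())
        h.update(np.float64(self.mu).tobytes())
        for arr in (self.prescale, self.zscore_mean, self.zscore_std):
            if arr is not None:
                h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
        return h.hexdigest()[:16]


def compute_rms_windows(
    emg: np.ndarray, fs: float, window_ms: float = DEFAULT_WINDOW_MS,
    step_ms: float = DEFAULT_STEP_MS,
) -> np.ndarray:
    """Sliding-window RMS envelope, one row per window.

    Windows are 0-based, half-open sample intervals [start, start + W);
    entry [w, c] = sqrt(mean(x[c, wS : wS+W]^2)).
    """
    emg = np.asarray(emg, dtype=float)
    if emg.ndim == 1:
        emg = emg[:, None]
    W = max(int(round(window_ms * fs / 1000.0)), 1)
    S = max(int(round(step_ms * fs / 1000.0)), 1)
    n = emg.shape[0]
    if n < W:
        raise ValueError(
            f"signal has {n} samples but one window needs {W} "
            f"({window_ms} ms at {fs} Hz)"
        )
    sq = np.lib.stride_tricks.sliding_window_view(emg**2, W, axis=0)  # [n-W+1, C, W]
    return np.sqrt(sq[::S].mean(axis=-1))


def mu_law_normalize(x: np.ndarray, mu: float = DEFAULT_MU) -> np.ndarray:
    """Odd logarithmic companding F(x) = sign(x) ln(1+mu|x|)/ln(1+mu) on [-1, 1]."""
    x = np.asarray(x, dtype=float)
    if mu <= 0:
        raise ValueError("mu must be positive")
    amax = np.max(np.abs(x)) if x.size else 0.0
    if amax > 1.0 + 1e-12:
        raise ValueError(
            f"mu-law input must lie in [-1, 1]; max |x| = {amax:.6g} "
            "(prescale misconfigured)"
        )
    return np.sign(x) * np.log1p(mu * np.abs(x)) / np.log1p(mu)


def mu_law_inverse(y: np.ndarray, mu: float = DEFAULT_MU) -> np.ndarray:
    """Exact inverse of :func:`mu_law_normalize`."""
    y = np.asarray(y, dtype=float)
    if mu <= 0:
        raise ValueError("mu must be positive")
    amax = np.max(np.abs(y)) if y.size else 0.0
    if amax > 1.0 + 1e-12:
        raise ValueError(f"mu-law inverse input must lie in [-1, 1]; max |y| = {amax:.6g}")
    return np.sign(y) * np.expm1(np.abs(y) * np.log1p(mu)) / mu


def zscore_normalize(x: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    """Per-channel standardization (x - mean) / std with frozen statistics."""
    x = np.asarray(x, dtype=float)
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    std = np.atleast_1d(np.asarray(std, dtype=float))
    bad = np.flatnonzero(std <= 0)
    if bad.size:
        raise ValueError(f"zero/negative std on channel(s) {bad.tolist()}")
    return (x - mean) / std


def resample_labels(
    angles: np.ndarray, fs_from: float, fs_to: float,
    window_ms: float | None = None, step_ms: float | None = None,
    n_windows: int | None = None,
) -> np.ndarray:
    """Linearly interpolate glove angles to fs_to; optionally align to windows.

    Without window arguments returns the dense upsampled series of length
    round(m * fs_to / fs_from).  With window/step (ms) and n_windows, returns
    one row per feature window, sampled at each window's centre timestamp.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.ndim == 1:
        angles = angles[:, None]
    m = angles.shape[0]
    if m < 2:
        raise ValueError(f"need at least 2 label samples to interpolate, got {m}")
    if fs_to < fs_from:
        raise ValueError("fs_to must be >= fs_from")
    t_src = np.arange(m) / fs_from
    if window_ms is None:
        n_out = int(round(m * fs_to / fs_from))
        t_out = np.arange(n_out) / fs_to
    else:
        if n_windows is None or step_ms is None:
            raise ValueError("window alignment needs step_ms and n_windows")
        W = window_ms / 1000.0
        S = step_ms / 1000.0
        t_out = np.arange(n_windows) * S + W / 2.0  # window-centre timestamps
    t_out = np.clip(t_out, t_src[0], t_src[-1])
    out = np.empty((t_out.size, angles.shape[1]))
    for j in range(angles.shape[1]):
        out[:, j] = np.interp(t_out, t_src, angles[:, j])
    return out


def split_trials(
    trials: "set[int] | list[int]", n_train: int = 4, n_test: int = 2,
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Random disjoint train/test partition of the six repetitions.

    Deterministic in ``seed``; a subject's movements share the partition by
    passing the same seed for each.
    """
    trials = sorted(trials)
    if len(trials) != n_train + n_test:
        raise ValueError(
            f"expected exactly {n_train + n_test} trials, got {len(trials)}: {trials}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(trials))
    train = sorted(trials[i] for i in perm[:n_train])
    test = sorted(trials[i] for i in perm[n_train:])
    return train, test


def fit_normalization(
    features_list: "list[np.ndarray]", method: str = "mu_law",
    mu: float = DEFAULT_MU,
) -> NormalizationSpec:
    """Fit per-channel normalization statistics on training RMS features."""
    stacked = np.vstack([np.asarray(f, dtype=float) for f in features_list])
    if method == "mu_law":
        prescale = np.max(np.abs(stacked), axis=0)
        prescale = np.where(prescale > 0, prescale, 1.0)
        return NormalizationSpec(method="mu_law", mu=mu, prescale=prescale)
    if method == "zscore":
        std = stacked.std(axis=0, ddof=0)
        bad = np.flatnonzero(std <= 0)
        if bad.size:
            raise ValueError(f"constant training channel(s) {bad.tolist()}: std is zero")
        return NormalizationSpec(
            method="zscore", mu=mu, zscore_mean=stacked.mean(axis=0), zscore_std=std
        )
    raise ValueError(f"unknown normalization method {method!r}")


def apply_normalization(features: np.ndarray, spec: NormalizationSpec) -> np.ndarray:
    """Apply a frozen NormalizationSpec; test-time values are clipped into range."""
    features = np.asarray(features, dtype=float)
    if spec.method == "mu_law":
        if spec.prescale is None:
            raise ValueError("mu_law spec has no fitted prescale")
        scaled = np.clip(features / spec.prescale, -1.0, 1.0)
        return mu_law_normalize(scaled, spec.mu)
    if spec.zscore_mean is None or spec.zscore_std is None:
        raise ValueError("zscore spec has no fitted statistics")
    return zscore_normalize(features, spec.zscore_mean, spec.zscore_std)


def prepare_features(
    rec: SubjectRecording, spec: NormalizationSpec,
    window_ms: float = DEFAULT_WINDOW_MS, step_ms: float = DEFAULT_STEP_MS,
) -> FeatureSeries:
    """Full per-recording pipeline: RMS windows, normalization, label alignment."""
    rms = compute_rms_windows(rec.emg, rec.fs_emg, window_ms, step_ms)
    feats = apply_normalization(rms, spec)
    labels = resample_labels(
        rec.angles, rec.fs_angles, rec.fs_emg,
        window_ms=window_ms, step_ms=step_ms, n_windows=rms.shape[0],
    )
    return FeatureSeries(
        features=feats, labels=labels, window_ms=window_ms, step_ms=step_ms,
        provenance=(rec.subject_id, rec.movement_id, rec.trial_id),
        norm_hash=spec.digest(),
    )


def raw_rms(rec: SubjectRecording, window_ms: float = DEFAULT_WINDOW_MS,
            step_ms: float = DEFAULT_STEP_MS) -> np.ndarray:
    """Un-normalized RMS features of one recording (for fitting statistics)."""
    return compute_rms_windows(rec.emg, rec.fs_emg, window_ms, step_ms)


# ---------------------------------------------------------------------------
# CSV round-trip


def save_feature_series(fs: FeatureSeries, directory: str | Path) -> None:
    """Write features.csv / labels.csv plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_ch = fs.features.shape[1]
    n_j = fs.labels.shape[1]
    pd.DataFrame(fs.features, columns=[f"ch{c + 1:02d}" for c in range(n_ch)]).to_csv(
        directory / "features.csv", index=False
    )
    pd.DataFrame(fs.labels, columns=[f"j{j + 1:02d}" for j in range(n_j)]).to_csv(
        directory / "labels.csv", index=False
    )
    meta = {
        "window_ms": fs.window_ms,
        "step_ms": fs.step_ms,
        "provenance": list(fs.provenance),
        "norm_hash": fs.norm_hash,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_feature_series(directory: str | Path) -> FeatureSeries:
    directory = Path(directory)
    feats = pd.read_csv(directory / "features.csv").to_numpy(dtype=float)
    labels = pd.read_csv(directory / "labels.csv").to_numpy(dtype=float)
    meta = json.loads((directory / "meta.json").read_text())
    return FeatureSeries(
        features=feats, labels=labels, window_ms=meta["window_ms"],
        step_ms=meta["step_ms"], provenance=tuple(meta["provenance"]),
        norm_hash=meta.get("norm_hash"),
    )
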
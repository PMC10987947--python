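"""Estimation-quality metrics: Pearson CC, range-normalized RMSE, R².

A prediction is scored per joint over the concatenated test windows of
one (subject, movement); per-joint values are then averaged.  NRMSE
divides RMSE by the observed range of the measured angle, so an
in-range predictor scores in [0, 1] for every joint regardless of its
excursion.  R² may be negative for worse-than-mean predictors and is
reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetricsReport",
    "pearson_cc",
    "nrmse",
    "r_squared",
    "evaluate_predictions",
    "evaluate_model",
    "aggregate_reports",
]


def _as_series(y, name: str) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2:
        raise ValueError(f"{name} needs length >= 2, got {y.size}")
    return y


def pearson_cc(y_true, y_pred) -> float:
    """Sample Pearson correlation between measured and estimated series."""
    yt = _as_series(y_true, "y_true")
    yp = _as_series(y_pred, "y_pred")
    if yt.size != yp.size:
        raise ValueError(f"length mismatch: {yt.size} vs {yp.size}")
    st, sp = yt.std(), yp.std()
    if st == 0:
        raise ValueError("y_true has zero variance")
    if sp == 0:
        raise ValueError("y_pred has zero variance")
    return float(np.mean((yt - yt.mean()) * (yp - yp.mean())) / (st * sp))


def nrmse(y_true, y_pred) -> float:
    """RMSE scaled by the observed range of y_true."""
    yt = _as_series(y_true, "y_true")
    yp = _as_series(y_pred, "y_pred")
    if yt.size != yp.size:
        raise ValueError(f"length mismatch: {yt.size} vs {yp.size}")
    rng = yt.max() - yt.min()
    if rng == 0:
        raise ValueError("y_true is constant; NRMSE undefined")
    return float(np.sqrt(np.mean((yt - yp) ** 2)) / rng)


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (negative allowed)."""
    yt = _as_series(y_true, "y_true")
    yp = _as_series(y_pred, "y_pred")
    if yt.size != yp.size:
        raise ValueError(f"length mismatch: {yt.size} vs {yp.size}")
    ss_tot = np.sum((yt - yt.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("y_true has zero variance")
    return float(1.0 - np.sum((yt - yp) ** 2) / ss_tot)


@dataclass
class MetricsReport:
    """Per-joint and joint-averaged CC/NRMSE/R² for one evaluation unit."""

    cc: np.ndarray  # [n_joints]
    nrmse: np.ndarray
    r2: np.ndarray
    grouping: dict = field(default_factory=dict)  # subject / movement / condition

    @property
    def ave_cc(self) -> float:
        return float(np.mean(self.cc))

    @property
    def ave_nrmse(self) -> float:
        return float(np.mean(self.nrmse))

    @property
    def ave_r2(self) -> float:
        return float(np.mean(self.r2))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j in range(len(self.cc)):
            rows.append({**self.grouping, "joint": f"j{j + 1:02d}",
                         "cc": self.cc[j], "nrmse": self.nrmse[j], "r2": self.r2[j]})
        return pd.DataFrame(rows)


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                         grouping: dict | None = None) -> MetricsReport:
    """Per-joint metrics over stacked windows [n, n_joints]."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    nj = y_true.shape[1]
    cc = np.array([pearson_cc(y_true[:, j], y_pred[:, j]) for j in range(nj)])
    nr = np.array([nrmse(y_true[:, j], y_pred[:, j]) for j in range(nj)])
    r2 = np.array([r_squared(y_true[:, j], y_pred[:, j]) for j in range(nj)])
    return MetricsReport(cc=cc, nrmse=nr, r2=r2, grouping=dict(grouping or {}))


def evaluate_model(model, test_data, grouping: dict | None = None,
                   per_movement: bool = False):
    """Score a trained regressor on a set of FeatureSeries.

    Windows are pooled across the given series (the model's stored
    normalization digest must match each series').  With
    ``per_movement=True`` one report per movement is returned instead.
    """
    series = list(test_data)
    if not series:
        raise ValueError("empty test set")
    model_hash = getattr(model, "norm_hash", None)
    for fs in series:
        if model_hash is not None and fs.norm_hash is not None and fs.norm_hash != model_hash:
            raise ValueError(
                f"normalization mismatch for {fs.provenance}: series "
                f"{fs.norm_hash} vs model {model_hash}"
            )
    if per_movement:
        by_mv: dict = {}
        for fs in series:
            by_mv.setdefault(fs.provenance[1], []).append(fs)
        return [
            evaluate_model(model, group, {**(grouping or {}), "movement": mv})
            for mv, group in sorted(by_mv.items())
        ]
    y_true = np.vstack([fs.labels for fs in series])
    y_pred = np.vstack([model.predict(fs.features) for fs in series])
    return evaluate_predictions(y_true, y_pred, grouping)


def aggregate_reports(reports) -> pd.DataFrame:
    """Mean ± across-report standard deviation of the averaged metrics."""
    rows = [{**r.grouping, "ave_cc": r.ave_cc, "ave_nrmse": r.ave_nrmse,
             "ave_r2": r.ave_r2} for r in reports]
    df = pd.DataFrame(rows)
    summary = {
        "ave_cc_mean": df["ave_cc"].mean(), "ave_cc_std": df["ave_cc"].std(ddof=0),
        "ave_nrmse_mean": df["ave_nrmse"].mean(), "ave_nrmse_std": df["ave_nrmse"].std(ddof=0),
        "ave_r2_mean": df["ave_r2"].mean(), "ave_r2_std": df["ave_r2"].std(ddof=0),
    }
    df.attrs["summary"] = summary
    return df
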
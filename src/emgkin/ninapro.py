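"""Reader for Ninapro DB2 MATLAB containers.

DB2 stores, per subject, continuous arrays: ``emg`` (12 channels at
2 kHz), ``glove`` (22 CyberGlove channels, upsampled to the EMG clock),
``stimulus`` (movement label per sample; 0 = rest) and ``repetition``
(trial label per sample).  The loader segments the continuous record at
stimulus-label boundaries into one ``SubjectRecording`` per
(movement, repetition), restricted to the 12 sEMG channels and a chosen
subset of 10 glove channels.

The defaults below for movements, glove channels, and subjects are
package choices a user can (and for serious use should) override:
six grasp movements from DB2 Exercise B's grasp set, and the ten
metacarpophalangeal/proximal-interphalangeal flexion sensors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import loadmat

from .signal_prep import SubjectRecording

__all__ = ["Db2Selection", "load_db2_recording", "segment_runs"]

N_EMG_CHANNELS = 12

# Exercise B grasp movements (cylindrical / spherical / flat objects,
# large-to-small diameters) — a documented default, not the (unpublished)
# selection any particular study used.
DEFAULT_MOVEMENTS = (5, 6, 9, 13, 17, 18)
# CyberGlove II MCP/PIP flexion sensors for thumb..little finger (1-based).
DEFAULT_GLOVE_CHANNELS = (1, 4, 7, 10, 13, 2, 5, 8, 11, 14)
DEFAULT_SUBJECTS = tuple(range(1, 11))


@dataclass
class Db2Selection:
    """Which movements, glove channels, and subjects to read."""

    movement_ids: tuple = DEFAULT_MOVEMENTS
    glove_channel_ids: tuple = DEFAULT_GLOVE_CHANNELS  # 1-based indices into 22
    subject_ids: tuple = DEFAULT_SUBJECTS

    def __post_init__(self) -> None:
        if len(self.movement_ids) != 6:
            raise ValueError(f"expected 6 movements, got {len(self.movement_ids)}")
        if len(self.glove_channel_ids) != 10:
            raise ValueError(
                f"expected 10 glove channels, got {len(self.glove_channel_ids)}"
            )
        if len(self.subject_ids) != 10:
            raise ValueError(f"expected 10 subjects, got {len(self.subject_ids)}")
        if not all(1 <= g <= 22 for g in self.glove_channel_ids):
            raise ValueError("glove channel ids must lie in 1..22")


def segment_runs(labels: np.ndarray):
    """Yield (value, start, stop) runs of a 1-D label array (half-open)."""
    labels = np.asarray(labels).ravel()
    if labels.size == 0:
        return
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [labels.size]])
    for s, e in zip(starts, stops):
        yield int(labels[s]), int(s), int(e)


def load_db2_recording(path, selection: Db2Selection | None = None,
                       subject_id: str | None = None,
                       data: dict | None = None) -> list:
    """Load one DB2 subject file into SubjectRecording values.

    ``data`` may supply an already-loaded container (for tests);
    otherwise ``path`` is read with scipy's MATLAB reader.  Rest
    segments (stimulus 0) are excluded; one record is emitted per
    (selected movement, repetition) run.
    """
    sel = selection or Db2Selection()
    if data is None:
        data = loadmat(str(path))
    for key in ("emg", "glove", "stimulus", "repetition"):
        if key not in data:
            raise KeyError(f"DB2 container is missing array {key!r}")
    emg = np.asarray(data["emg"], dtype=float)
    glove = np.asarray(data["glove"], dtype=float)
    stimulus = np.asarray(data["stimulus"]).ravel().astype(int)
    repetition = np.asarray(data["repetition"]).ravel().astype(int)
    if emg.shape[1] != N_EMG_CHANNELS:
        raise ValueError(
            f"expected {N_EMG_CHANNELS} sEMG channels, file has {emg.shape[1]}"
        )
    if glove.shape[1] < max(sel.glove_channel_ids):
        raise ValueError(
            f"glove has {glove.shape[1]} channels; selection needs "
            f"channel {max(sel.glove_channel_ids)}"
        )
    if not (emg.shape[0] == glove.shape[0] == stimulus.size == repetition.size):
        raise ValueError("emg/glove/stimulus/repetition lengths disagree")

    present = set(np.unique(stimulus)) - {0}
    missing = set(sel.movement_ids) - present
    if missing:
        raise ValueError(f"movement id(s) {sorted(missing)} absent from file")

    sid = subject_id or Path(str(path)).stem
    glove_idx = [g - 1 for g in sel.glove_channel_ids]
    records = []
    for value, start, stop in segment_runs(stimulus):
        if value == 0 or value not in sel.movement_ids:
            continue
        reps = np.unique(repetition[start:stop])
        reps = reps[reps > 0]
        rep = int(reps[0]) if reps.size else 0
        # glove is stored on the EMG clock in DB2 files
        records.append(SubjectRecording(
            subject_id=sid, movement_id=f"M{value}", trial_id=rep,
            emg=emg[start:stop], angles=glove[start:stop][:, glove_idx],
            fs_emg=2000.0, fs_angles=2000.0,
        ))
    return records
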
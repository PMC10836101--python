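"""Core data carriers shared across the pipeline.

``EpochedRecording`` is the common in-memory form for both resting EEG
(non-overlapping 2 s epochs cut from a continuous recording) and chirp EEG
(one epoch per stimulus trial, time-locked to stimulus onset).  Feature
tables are plain :class:`pandas.DataFrame` objects with a small set of
reserved metadata columns; helpers here validate and split them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: reserved metadata columns of a feature table, in canonical order
META_COLUMNS = ["participant_id", "group", "sex", "mosaic"]

GROUP_FXS = "FXS"
GROUP_CON = "CON"


@dataclass
class EpochedRecording:
    """Multichannel epoched EEG in microvolts.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_epochs, n_samples)`` in µV.
    sfreq
        Sampling rate in Hz.
    ch_names
        Unique channel labels, one per data row.
    montage
        Montage identifier, e.g. ``"hydrocel128"`` or ``"standard1020-20"``.
    task
        ``"rest"`` or ``"chirp"``.
    tmin
        Time of the first sample of each epoch relative to stimulus onset
        (chirp) or epoch start (rest, conventionally 0).
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    montage: str = "unknown"
    task: str = "rest"
    tmin: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (n_channels, n_epochs, n_samples); got shape {self.data.shape}"
            )
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        self.ch_names = list(self.ch_names)
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("number of channel labels does not match data")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if self.task not in ("rest", "chirp"):
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.sfreq

    @property
    def epoch_duration(self) -> float:
        return self.n_samples / self.sfreq

    def pick(self, labels) -> "EpochedRecording":
        """Return a sub-recording restricted to ``labels`` (label order kept)."""
        labels = list(labels)
        missing = [lb for lb in labels if lb not in self.ch_names]
        if missing:
            raise KeyError(f"channels not in recording: {missing}")
        idx = [self.ch_names.index(lb) for lb in labels]
        return EpochedRecording(
            self.data[idx], self.sfreq, labels, self.montage, self.task, self.tmin, dict(self.meta)
        )


def validate_feature_table(table: pd.DataFrame, features=None) -> list[str]:
    """Check a feature table and return its feature column names.

    A feature table holds one row per participant: the reserved metadata
    columns (``participant_id``, ``group``, ``sex``, ``mosaic``) followed by
    named EEG variables.
    """
    if not isinstance(table, pd.DataFrame):
        raise TypeError("feature table must be a pandas DataFrame")
    missing = [c for c in ("participant_id", "group") if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing required columns: {missing}")
    cols = [c for c in table.columns if c not in META_COLUMNS]
    if features is not None:
        absent = [f for f in features if f not in table.columns]
        if absent:
            raise KeyError(f"features not in table: {absent}")
        cols = list(features)
    bad = [c for c in cols if table[c].isna().any()]
    if bad:
        raise ValueError(f"feature columns contain missing values: {bad}")
    return cols


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]
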
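"""Core containers: a multichannel recording with an aligned hypnogram,
and a set of labeled fixed-length epochs.

Five-state label coding: W=1, AS1=2, QS1=3, QS2=4, AS2=5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["STATE_CODES", "CODE_NAMES", "DEFAULT_CHANNELS", "Recording", "EpochSet"]

STATE_CODES: dict[str, int] = {"W": 1, "AS1": 2, "QS1": 3, "QS2": 4, "AS2": 5}
CODE_NAMES: dict[int, str] = {v: k for k, v in STATE_CODES.items()}

#: the eight 10–20 scalp electrodes used throughout (odd = left hemisphere)
DEFAULT_CHANNELS = ("C3", "C4", "F3", "F4", "P3", "P4", "T3", "T4")


@dataclass
class Recording:
    """Multichannel EEG signal (µV) with a per-epoch hypnogram.

    ``data`` is channels × samples; the hypnogram has one code in 1..5
    per ``epoch_s``-second scoring window.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str
    hypnogram: np.ndarray
    epoch_s: float = 30.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.hypnogram = np.asarray(self.hypnogram, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match data rows")
        bad = set(np.unique(self.hypnogram)) - set(CODE_NAMES)
        if bad:
            raise ValueError(f"hypnogram contains invalid codes {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Labeled fixed-length epochs: n_epochs × n_channels × n_samples."""

    epochs: np.ndarray
    labels: np.ndarray
    fs: float
    epoch_s: float
    channel_names: list[str]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be n_epochs x n_channels x n_samples")
        if self.epochs.shape[0] != self.labels.size:
            raise ValueError("one label per epoch required")
        expected = int(round(self.fs * self.epoch_s))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} != fs*epoch_s = {expected}"
            )
        if not self.subject_ids:
            self.subject_ids = ["?"] * self.epochs.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]
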
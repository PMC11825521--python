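"""Band-pass filtering and 30-s segmentation of EEG recordings.

The filter is a linear-phase windowed-sinc FIR band-pass (0.3–35 Hz by
default, Hamming window, order set from a 0.25 Hz transition band at the
low edge). The symmetric kernel is applied by centered overlap-add
convolution, which cancels the group delay exactly — zero phase in one
pass — so epoch boundaries stay aligned with the hypnogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .recording import EpochSet, Recording

__all__ = ["FilterSpec", "bandpass", "segment", "select_channels"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """FIR band-pass design: passband [low_cut, high_cut] Hz."""

    low_cut: float = 0.3
    high_cut: float = 35.0
    window: str = "hamming"
    transition_hz: float = 0.25
    numtaps: int | None = None  # default: set from transition_hz
    zero_phase: bool = True

    def taps(self, fs: float) -> np.ndarray:
        if not 0 < self.low_cut < self.high_cut < fs / 2:
            raise ValueError(
                f"need 0 < low_cut < high_cut < fs/2, got "
                f"({self.low_cut}, {self.high_cut}) at fs={fs}"
            )
        if self.numtaps is None:
            # Hamming window: ~3.3 / (transition width in normalized freq)
            n = int(np.ceil(3.3 * fs / self.transition_hz))
            n += 1 - n % 2  # odd length -> integer group delay, type-I FIR
        else:
            n = self.numtaps
        return sps.firwin(
            n,
            [self.low_cut, self.high_cut],
            window=self.window,
            pass_zero=False,
            fs=fs,
        )


def bandpass(recording: Recording, filt: FilterSpec | None = None) -> Recording:
    """Return a copy of the recording with every channel band-pass
    filtered. Zero-phase: the symmetric FIR kernel is applied with
    centered (mode='same') overlap-add convolution."""
    filt = filt or FilterSpec()
    taps = filt.taps(recording.fs)
    if recording.n_samples <= taps.size:
        raise ValueError(
            f"recording has {recording.n_samples} samples; the filter "
            f"requires more than {taps.size}"
        )
    filtered = np.stack(
        [sps.oaconvolve(ch, taps, mode="same") for ch in recording.data]
    )
    return replace(recording, data=filtered)


def segment(recording: Recording, epoch_s: float | None = None) -> EpochSet:
    """Cut a recording into labeled epochs, one per hypnogram entry.

    A trailing remainder shorter than one epoch is dropped with a logged
    warning; a mismatch beyond one partial epoch is an error. Epochs
    containing any non-finite sample are rejected (with a logged count).
    """
    epoch_s = epoch_s if epoch_s is not None else recording.epoch_s
    spe = int(round(recording.fs * epoch_s))
    if abs(recording.fs * epoch_s - spe) > 1e-9:
        raise ValueError("fs * epoch_s must be an integer sample count")
    n_epochs = len(recording.hypnogram)
    expected = n_epochs * spe
    if recording.n_samples < expected or recording.n_samples >= expected + spe:
        raise ValueError(
            f"{recording.n_samples} samples inconsistent with "
            f"{n_epochs} epochs of {spe} samples (allowed: up to one "
            f"trailing partial epoch)"
        )
    dropped = recording.n_samples - expected
    if dropped:
        logger.warning(
            "subject %s: dropping trailing %.3g s (< one epoch)",
            recording.subject_id,
            dropped / recording.fs,
        )
    cube = recording.data[:, :expected].reshape(recording.n_channels, n_epochs, spe)
    cube = np.moveaxis(cube, 0, 1)  # -> epochs x channels x samples
    finite = np.isfinite(cube).all(axis=(1, 2))
    if not finite.all():
        logger.warning(
            "subject %s: rejecting %d epoch(s) with non-finite samples",
            recording.subject_id,
            int((~finite).sum()),
        )
    return EpochSet(
        epochs=cube[finite],
        labels=recording.hypnogram[finite],
        fs=recording.fs,
        epoch_s=epoch_s,
        channel_names=list(recording.channel_names),
        subject_ids=[recording.subject_id] * int(finite.sum()),
    )


def select_channels(epochs: EpochSet, names: list[str]) -> EpochSet:
    """Restrict and reorder the channel axis to ``names``."""
    missing = [n for n in names if n not in epochs.channel_names]
    if missing:
        raise ValueError(
            f"unknown channel(s) {missing}; available: {list(epochs.channel_names)}"
        )
    idx = [epochs.channel_names.index(n) for n in names]
    return EpochSet(
        epochs=epochs.epochs[:, idx, :],
        labels=epochs.labels.copy(),
        fs=epochs.fs,
        epoch_s=epochs.epoch_s,
        channel_names=list(names),
        subject_ids=list(epochs.subject_ids),
    )


def concat_epoch_sets(sets: list[EpochSet]) -> EpochSet:
    """Pool epochs from several recordings (same fs, epoch_s, channels)."""
    first = sets[0]
    for s in sets[1:]:
        if s.channel_names != first.channel_names or s.fs != first.fs:
            raise ValueError("epoch sets are not compatible")
    return EpochSet(
        epochs=np.concatenate([s.epochs for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        fs=first.fs,
        epoch_s=first.epoch_s,
        channel_names=list(first.channel_names),
        subject_ids=sum((list(s.subject_ids) for s in sets), []),
    )
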
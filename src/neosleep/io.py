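"""Reading and writing recordings.

EDF (European Data Format) support is a minimal, self-contained
implementation of the 16-bit EDF standard: fixed-width ASCII header,
one-second data records, little-endian int16 samples with per-signal
physical/digital scaling. Files written here open in standard EDF
readers (the test suite cross-reads them with MNE). Hypnograms travel in
a delimited sidecar with columns
``epoch_index, onset_s, duration_s, label_code, label_name``, because
base EDF has no annotation channel.

A plain delimited format (samples × channels TSV) is provided for raw
numeric exchange.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import CODE_NAMES, Recording

__all__ = [
    "write_edf",
    "read_edf",
    "write_labels",
    "read_labels",
    "write_recording",
    "read_recording",
    "write_delimited",
    "read_delimited",
]


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _num8(value: float) -> bytes:
    """A float in at most 8 ASCII chars."""
    for fmt in ("%g", "%.5g", "%.4g", "%.3g", "%.2g"):
        s = fmt % value
        if len(s) <= 8:
            return s.ljust(8).encode("ascii")
    raise ValueError(f"cannot format {value} in 8 chars")


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF, one-second data records,
    physical dimension µV."""
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = recording.n_samples // fs
    if n_records * fs != recording.n_samples:
        raise ValueError("signal length must be a whole number of seconds")
    ns = recording.n_channels

    dmin, dmax = -32768, 32767
    phys_min = recording.data.min(axis=1)
    phys_max = recording.data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_max[flat] = phys_min[flat] + 1.0

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(recording.subject_id, 80),
            _ascii("neosleep synthetic EEG", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (ns + 1), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),
            _ascii(ns, 4),
        ]
    )
    fields = [
        [_ascii(name, 16) for name in recording.channel_names],
        [_ascii("AgAgCl electrode", 80)] * ns,
        [_ascii("uV", 8)] * ns,
        [_num8(v) for v in phys_min],
        [_num8(v) for v in phys_max],
        [_ascii(dmin, 8)] * ns,
        [_ascii(dmax, 8)] * ns,
        [_ascii("", 80)] * ns,
        [_ascii(fs, 8)] * ns,
        [_ascii("", 32)] * ns,
    ]
    signal_header = b"".join(b"".join(f) for f in fields)

    scale = (dmax - dmin) / (phys_max - phys_min)
    digital = np.rint(
        (recording.data - phys_min[:, None]) * scale[:, None] + dmin
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str], str]:
    """Read a 16-bit EDF file; returns (data channels × samples, fs,
    channel names, subject id). All signals must share one rate."""
    raw = Path(path).read_bytes()
    subject_id = raw[8:88].decode("ascii").strip()
    n_records = int(raw[236:244])
    record_dur = float(raw[244:252])
    ns = int(raw[252:256])

    off = 256

    def field(width):
        nonlocal off
        vals = [raw[off + i * width : off + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)]
        off += ns * width
        return vals

    labels = field(16)
    field(80)  # transducer
    field(8)  # dimension
    phys_min = np.array([float(v) for v in field(8)])
    phys_max = np.array([float(v) for v in field(8)])
    dig_min = np.array([float(v) for v in field(8)])
    dig_max = np.array([float(v) for v in field(8)])
    field(80)  # prefiltering
    spr = np.array([int(v) for v in field(8)])  # samples per record
    field(32)
    if len(set(spr)) != 1:
        raise ValueError("mixed sampling rates are not supported")
    spr0 = int(spr[0])
    fs = spr0 / record_dur

    data = np.empty((ns, n_records * spr0))
    body = np.frombuffer(raw, dtype="<i2", offset=256 * (ns + 1))
    body = body.reshape(n_records, ns, spr0)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    for c in range(ns):
        data[c] = (body[:, c, :].ravel() - dig_min[c]) * gain[c] + phys_min[c]
    return data, fs, labels, subject_id


def write_labels(recording: Recording, path: str | Path) -> None:
    """Hypnogram sidecar: one row per scored epoch."""
    rows = [
        {
            "epoch_index": i,
            "onset_s": i * recording.epoch_s,
            "duration_s": recording.epoch_s,
            "label_code": int(code),
            "label_name": CODE_NAMES[int(code)],
        }
        for i, code in enumerate(recording.hypnogram)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels(path: str | Path) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path)
    return df["label_code"].to_numpy(dtype=int), float(df["duration_s"].iloc[0])


def write_recording(recording: Recording, out_dir: str | Path) -> tuple[Path, Path]:
    """EDF + label sidecar, named after the subject id."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edf = out / f"{recording.subject_id}.edf"
    labels = out / f"{recording.subject_id}_labels.csv"
    write_edf(recording, edf)
    write_labels(recording, labels)
    return edf, labels


def read_recording(edf_path: str | Path, labels_path: str | Path) -> Recording:
    data, fs, channels, subject_id = read_edf(edf_path)
    hypnogram, epoch_s = read_labels(labels_path)
    return Recording(
        data=data,
        fs=fs,
        channel_names=channels,
        subject_id=subject_id,
        hypnogram=hypnogram,
        epoch_s=epoch_s,
    )


def write_delimited(recording: Recording, path: str | Path) -> None:
    """Raw numeric exchange: TSV, samples × channels, header row."""
    pd.DataFrame(recording.data.T, columns=recording.channel_names).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def read_delimited(
    path: str | Path,
    labels_path: str | Path,
    fs: float,
    subject_id: str = "raw",
) -> Recording:
    df = pd.read_csv(path, sep="\t")
    hypnogram, epoch_s = read_labels(labels_path)
    return Recording(
        data=df.to_numpy().T,
        fs=fs,
        channel_names=list(df.columns),
        subject_id=subject_id,
        hypnogram=hypnogram,
        epoch_s=epoch_s,
    )
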
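"""EEG and table I/O: the :class:`Recording` container and format codecs.

All potentials are held internally in microvolts (µV) and time is
sample-indexed; readers convert from whatever unit the file declares.
Supported on-disk formats are BrainVision (``.vhdr``/``.vmrk``/``.eeg``,
IEEE float32) and EDF (16-bit). Reading goes through MNE; writing uses
compact in-package codecs so that write → read is an identity up to the
codec's declared precision.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "RecordingFormatError",
    "BehaviorError",
    "read_recording",
    "write_recording",
    "read_behavior",
    "write_table",
    "edf_quantization_step",
]

SESSIONS = ("T1", "T2")

#: required columns of a behavior table
BEHAVIOR_COLUMNS = ("subject_id", "session", "vocab_percent", "age", "group")


class RecordingFormatError(ValueError):
    """An EEG file could not be read or written under the named standard."""


class BehaviorError(ValueError):
    """A behavior table failed validation."""


@dataclass
class Recording:
    """A multichannel EEG segment.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Potentials in microvolts.
    srate : float
        Sampling rate in Hz.
    channel_labels : list of str
        Ordered channel names (10–20 convention where applicable).
    channel_positions : ndarray, shape (n_channels, 3), optional
        Unit-sphere electrode coordinates, required by spherical
        interpolation.
    subject_id : str
    session : str
        One of ``"T1"``/``"T2"``.
    """

    data: np.ndarray
    srate: float
    channel_labels: list[str]
    channel_positions: np.ndarray | None = None
    subject_id: str = ""
    session: str = "T1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels × samples array")
        self.channel_labels = list(self.channel_labels)
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.data.shape[0] == 0:
            raise ValueError("recording has zero channels")
        if not self.srate > 0:
            raise ValueError("srate must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}")
        if self.channel_positions is not None:
            pos = np.asarray(self.channel_positions, dtype=np.float64)
            if pos.shape != (self.n_channels, 3):
                raise ValueError("channel_positions must be n_channels × 3")
            norms = np.linalg.norm(pos, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("channel_positions must have unit norm (±1e-6)")
            self.channel_positions = pos

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate

    def copy_with(self, data: np.ndarray) -> "Recording":
        """Return a copy of this recording carrying new sample data."""
        return Recording(
            data=data,
            srate=self.srate,
            channel_labels=list(self.channel_labels),
            channel_positions=None
            if self.channel_positions is None
            else self.channel_positions.copy(),
            subject_id=self.subject_id,
            session=self.session,
        )

    def crop(self, start: int, stop: int) -> "Recording":
        """Sample-indexed half-open slice [start, stop)."""
        return self.copy_with(self.data[:, start:stop].copy())


# ---------------------------------------------------------------------------
# reading (MNE-backed)
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".vhdr":
        return "brainvision"
    if suffix in (".edf",):
        return "edf"
    raise RecordingFormatError(
        f"cannot infer format of {path}; pass format='brainvision' or 'edf'"
    )


def read_recording(
    path: str | Path,
    format: str | None = None,
    subject_id: str = "",
    session: str = "T1",
) -> Recording:
    """Read an EEG file into a :class:`Recording` (values in µV).

    Channels keep file order. Non-finite samples in the file raise a
    :class:`RecordingFormatError` rather than propagating silently.
    """
    import mne

    path = Path(path)
    fmt = format or _infer_format(path)
    if not path.exists():
        raise RecordingFormatError(f"no such file: {path}")
    try:
        if fmt == "brainvision":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        elif fmt == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raise RecordingFormatError(f"unknown format {fmt!r}")
    except RecordingFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise RecordingFormatError(f"could not read {path} as {fmt}: {exc}") from exc
    data = raw.get_data() * 1e6  # MNE holds volts; we hold µV
    if data.shape[0] == 0:
        raise RecordingFormatError(f"{path} contains zero channels")
    if not np.isfinite(data).all():
        bad = int(np.flatnonzero(~np.isfinite(data).all(axis=0))[0])
        raise RecordingFormatError(
            f"{path}: non-finite samples (first at sample offset {bad})"
        )
    return Recording(
        data=data,
        srate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=subject_id,
        session=session,
    )


# ---------------------------------------------------------------------------
# writing (in-package codecs)
# ---------------------------------------------------------------------------


def edf_quantization_step(data: np.ndarray) -> np.ndarray:
    """Per-channel quantization step of the 16-bit EDF codec, (range)/2**15."""
    lo, hi = _edf_physical_range(np.asarray(data))
    return (hi - lo) / 2**16 * 2


def _edf_physical_range(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = data.min(axis=1)
    hi = data.max(axis=1)
    flat = hi - lo <= 0
    lo = np.where(flat, lo - 1.0, lo)
    hi = np.where(flat, hi + 1.0, hi)
    return lo, hi


def _fixed(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        # EDF numeric fields are fixed-width ASCII; shorten floats to fit
        s = f"{float(value):.{max(width - 8, 1)}g}"[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    n_ch = rec.n_channels
    srate = rec.srate
    if abs(srate - round(srate)) > 1e-9:
        raise RecordingFormatError("EDF writer requires an integer sampling rate")
    spr = int(round(srate))  # 1-s data records
    if rec.n_samples % spr != 0:
        raise RecordingFormatError(
            "EDF writer requires a whole number of seconds "
            f"({rec.n_samples} samples at {spr} Hz)"
        )
    n_rec = rec.n_samples // spr
    lo, hi = _edf_physical_range(rec.data)
    dmin, dmax = -32768, 32767
    scale = (hi - lo) / (dmax - dmin)
    digital = np.round((rec.data - lo[:, None]) / scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    hdr = b""
    hdr += _fixed(0, 8)
    hdr += _fixed("X", 80)  # patient
    hdr += _fixed("X", 80)  # recording
    hdr += _fixed("01.01.00", 8)
    hdr += _fixed("00.00.00", 8)
    hdr += _fixed(256 * (1 + n_ch), 8)
    hdr += _fixed("", 44)
    hdr += _fixed(n_rec, 8)
    hdr += _fixed(1, 8)  # record duration, seconds
    hdr += _fixed(n_ch, 4)
    for lab in rec.channel_labels:
        hdr += _fixed(lab[:16], 16)
    hdr += b"".join(_fixed("", 80) for _ in range(n_ch))
    hdr += b"".join(_fixed("uV", 8) for _ in range(n_ch))
    for v in lo:
        hdr += _fixed(f"{v:.6g}"[:8], 8)
    for v in hi:
        hdr += _fixed(f"{v:.6g}"[:8], 8)
    hdr += b"".join(_fixed(dmin, 8) for _ in range(n_ch))
    hdr += b"".join(_fixed(dmax, 8) for _ in range(n_ch))
    hdr += b"".join(_fixed("", 80) for _ in range(n_ch))
    hdr += b"".join(_fixed(spr, 8) for _ in range(n_ch))
    hdr += b"".join(_fixed("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())  # channel-sequential within record


_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by restwise

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_ch}
SamplingInterval={interval}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channels}
"""

_VMRK_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
Mk1=New Segment,,1,1,0,20000101000000000000
"""


def _write_brainvision(rec: Recording, path: Path) -> None:
    stem = path.stem
    interval = 1e6 / rec.srate  # µs
    interval_s = f"{interval:.6f}".rstrip("0").rstrip(".")
    chan_lines = "\n".join(
        f"Ch{i + 1}={lab},,1,µV" for i, lab in enumerate(rec.channel_labels)
    )
    path.write_text(
        _VHDR_TEMPLATE.format(
            stem=stem, n_ch=rec.n_channels, interval=interval_s, channels=chan_lines
        ),
        encoding="utf-8",
    )
    path.with_suffix(".vmrk").write_text(
        _VMRK_TEMPLATE.format(stem=stem), encoding="utf-8"
    )
    # multiplexed float32: sample-major, channels interleaved
    path.with_suffix(".eeg").write_bytes(
        np.ascontiguousarray(rec.data.T, dtype="<f4").tobytes()
    )


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write a :class:`Recording` to disk; returns the header/file path.

    BrainVision files are IEEE float32 (quantization-free at float32
    precision); EDF is 16-bit with a per-channel step of
    (physical range)/2^15.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        if fmt == "edf":
            _write_edf(rec, path)
        elif fmt == "brainvision":
            _write_brainvision(rec, path)
        else:
            raise RecordingFormatError(f"unknown format {fmt!r}")
    except OSError as exc:
        raise RecordingFormatError(f"could not write {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# behavior tables
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_behavior(path: str | Path) -> pd.DataFrame:
    """Read and validate a behavior table (CSV/TSV with header).

    Required columns: subject_id, session, vocab_percent, age, group.
    Raises :class:`BehaviorError` naming the offending row on bad cells.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise BehaviorError(f"{path}: missing columns {missing}")
    for col in ("vocab_percent", "age"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise BehaviorError(
                f"{path}: non-numeric {col} in data row {int(bad[0]) + 1}"
            )
        df[col] = coerced
    out_of_range = df.index[
        (df["vocab_percent"] < 0) | (df["vocab_percent"] > 100)
    ]
    if len(out_of_range):
        raise BehaviorError(
            f"{path}: vocab_percent outside [0, 100] in data row "
            f"{int(out_of_range[0]) + 1}"
        )
    bad_sess = df.index[~df["session"].isin(SESSIONS)]
    if len(bad_sess):
        raise BehaviorError(
            f"{path}: unknown session in data row {int(bad_sess[0]) + 1}"
        )
    dupes = df.duplicated(subset=["subject_id", "session"])
    if dupes.any():
        raise BehaviorError(
            f"{path}: duplicate (subject_id, session) in data row "
            f"{int(df.index[dupes][0]) + 1}"
        )
    df["subject_id"] = df["subject_id"].astype(str)
    return df.reset_index(drop=True)


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write any result table as delimited text (UTF-8, header row)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=_sep_for(path), index=False)
    return path
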
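"""Data model and file I/O for multimodal neonatal recordings.

A :class:`Recording` bundles the three wearable modalities — chest ECG,
abdominal respiration and triaxial wrist acceleration — sampled
synchronously at a common rate (250 Hz on the acquisition platform this
package models).  Seizure ground truth is an :class:`AnnotationSet` of
half-open ``[onset_s, offset_s)`` intervals in seconds from recording
start.

Recordings are stored as EDF (the physiological-recording standard;
written by :mod:`neoseize._edf`, read back via :func:`mne.io.read_raw_edf`)
or as a plain CSV debug dialect with header
``t_s,ecg,resp,acc_x,acc_y,acc_z``.  Annotations are CSV with header
``onset_s,offset_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._edf import write_edf

#: canonical channel order in files
CHANNELS = ("ECG", "RESP", "ACC_X", "ACC_Y", "ACC_Z")
_EDF_UNITS = ("mV", "a.u.", "g", "g", "g")


class ChannelError(ValueError):
    """A required channel is missing or inconsistent with the others."""


class AnnotationError(ValueError):
    """An annotation row violates onset < offset or ordering constraints."""


@dataclass
class Signal:
    """A single uniformly sampled channel.

    Parameters
    ----------
    samples : ndarray of float
        Amplitude sequence; must be finite.
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        Channel name.
    start_time : float
        Offset of the first sample in seconds from recording start.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Signal samples must be 1-D")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError(f"channel {self.label!r} contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.fs

    def slice(self, start_s: float, end_s: float) -> "Signal":
        """Return the sub-signal covering ``[start_s, end_s)``."""
        i0 = int(round((start_s - self.start_time) * self.fs))
        i1 = int(round((end_s - self.start_time) * self.fs))
        if i0 < 0 or i1 > len(self.samples):
            raise ValueError(
                f"slice [{start_s}, {end_s}) s outside channel {self.label!r} "
                f"of duration {self.duration_s} s"
            )
        return Signal(self.samples[i0:i1], self.fs, self.label, start_s)


@dataclass
class TriaxialSignal:
    """Three accelerometer axes with identical rate and length."""

    x: Signal
    y: Signal
    z: Signal

    def __post_init__(self):
        lens = {len(a.samples) for a in (self.x, self.y, self.z)}
        rates = {a.fs for a in (self.x, self.y, self.z)}
        if len(lens) != 1 or len(rates) != 1:
            raise ChannelError("triaxial axes must share one length and sampling rate")

    @property
    def fs(self) -> float:
        return self.x.fs

    @property
    def duration_s(self) -> float:
        return self.x.duration_s

    def slice(self, start_s: float, end_s: float) -> "TriaxialSignal":
        return TriaxialSignal(
            self.x.slice(start_s, end_s),
            self.y.slice(start_s, end_s),
            self.z.slice(start_s, end_s),
        )


@dataclass
class Recording:
    """Synchronized multimodal recording for one subject."""

    subject_id: str
    ecg: Signal
    resp: Signal
    acc: TriaxialSignal

    def __post_init__(self):
        rates = {self.ecg.fs, self.resp.fs, self.acc.fs}
        if len(rates) != 1:
            raise ChannelError(f"channels must share one sampling rate, got {sorted(rates)}")
        durs = [self.ecg.duration_s, self.resp.duration_s, self.acc.duration_s]
        if max(durs) - min(durs) > 1.0 / self.ecg.fs:
            raise ChannelError(
                f"channel durations differ by more than one sample period: {durs}"
            )

    @property
    def fs(self) -> float:
        return self.ecg.fs

    @property
    def duration_s(self) -> float:
        return self.ecg.duration_s


@dataclass
class AnnotationSet:
    """Ordered, non-overlapping half-open seizure intervals in seconds."""

    intervals: list = field(default_factory=list)

    def __post_init__(self):
        ivs = [(float(a), float(b)) for a, b in self.intervals]
        for i, (a, b) in enumerate(ivs):
            if not b > a:
                raise AnnotationError(f"interval {i}: offset {b} must exceed onset {a}")
        if any(ivs[i + 1][0] < ivs[i][0] for i in range(len(ivs) - 1)):
            raise AnnotationError("intervals must be sorted by onset")
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


# ---------------------------------------------------------------------------
# recordings


def _channels_of(rec: Recording) -> list[Signal]:
    return [rec.ecg, rec.resp, rec.acc.x, rec.acc.y, rec.acc.z]


def write_recording(rec: Recording, path, format: str = "edf") -> None:
    """Write a Recording as EDF or as the CSV debug dialect."""
    if len(rec.ecg.samples) == 0:
        raise ValueError("zero-length recordings cannot be written")
    path = Path(path)
    arrays = [ch.samples for ch in _channels_of(rec)]
    if format == "edf":
        write_edf(path, arrays, list(CHANNELS), list(_EDF_UNITS), rec.fs)
    elif format == "csv":
        t = np.arange(len(arrays[0])) / rec.fs
        df = pd.DataFrame(
            dict(zip(["t_s", "ecg", "resp", "acc_x", "acc_y", "acc_z"], [t] + arrays))
        )
        df.to_csv(path, index=False, float_format="%.9g")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'edf' or 'csv'")


# mne rescales recognised physical dimensions to SI; undo to file units
_UNIT_FACTOR = {"mV": 1e3, "uV": 1e6, "V": 1.0}


def _read_edf(path: Path, subject_id: str) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    upper = {name.upper(): name for name in raw.ch_names}
    missing = [ch for ch in CHANNELS if ch not in upper]
    if missing:
        raise ChannelError(f"missing channel(s) {', '.join(missing)} in {path}")
    fs = float(raw.info["sfreq"])
    orig_units = dict(getattr(raw, "_orig_units", {}) or {})
    sigs = []
    for ch in CHANNELS:
        name = upper[ch]
        data = raw.get_data(picks=[name])[0]
        data = data * _UNIT_FACTOR.get(orig_units.get(name, ""), 1.0)
        sigs.append(Signal(data, fs, ch))
    return _assemble(sigs, subject_id)


def _read_csv(path: Path, subject_id: str, fs: float | None) -> Recording:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    wanted = ["ecg", "resp", "acc_x", "acc_y", "acc_z"]
    missing = [w for w in wanted if w not in cols]
    if missing:
        raise ChannelError(
            f"missing channel(s) {', '.join(m.upper() for m in missing)} in {path}"
        )
    if fs is None:
        if "t_s" not in cols or len(df) < 2:
            raise ValueError("CSV loading needs an explicit fs or a t_s column")
        dt = np.diff(df[cols["t_s"]].to_numpy())
        # round away the float noise of a printed time column
        fs = round(1.0 / float(np.median(dt)), 3)
    sigs = [
        Signal(df[cols[w]].to_numpy(dtype=float), float(fs), w.upper()) for w in wanted
    ]
    return _assemble(sigs, subject_id)


def _assemble(sigs: Sequence[Signal], subject_id: str) -> Recording:
    ecg, resp, ax, ay, az = sigs
    return Recording(subject_id, ecg, resp, TriaxialSignal(ax, ay, az))


def load_recording(
    path, format: str | None = None, subject_id: str | None = None, fs: float | None = None
) -> Recording:
    """Load a Recording from EDF or CSV.

    ``format`` defaults to the file suffix; ``subject_id`` to the file stem.
    For CSV without a ``t_s`` column, pass ``fs`` explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or path.suffix.lstrip(".").lower()
    sid = subject_id if subject_id is not None else path.stem
    if fmt == "edf":
        return _read_edf(path, sid)
    if fmt == "csv":
        return _read_csv(path, sid, fs)
    raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'csv'")


# ---------------------------------------------------------------------------
# annotations


def load_annotations(path) -> AnnotationSet:
    """Load seizure intervals from a CSV with header ``onset_s,offset_s``.

    Overlap is rejected here; merging of nearby seizures is an epoching
    concern, not an I/O one.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "onset_s" not in cols or "offset_s" not in cols:
        raise AnnotationError(f"{path}: expected columns onset_s, offset_s")
    rows = list(
        zip(df[cols["onset_s"]].astype(float), df[cols["offset_s"]].astype(float))
    )
    for i, (a, b) in enumerate(rows, start=1):
        if not b > a:
            raise AnnotationError(f"{path}: row {i}: offset {b} ≤ onset {a}")
    rows.sort(key=lambda iv: iv[0])
    for i in range(len(rows) - 1):
        if rows[i + 1][0] < rows[i][1]:
            raise AnnotationError(
                f"{path}: rows overlap: {rows[i]} and {rows[i + 1]}"
            )
    return AnnotationSet(rows)


def write_annotations(ann: AnnotationSet, path) -> None:
    pd.DataFrame(ann.intervals, columns=["onset_s", "offset_s"]).to_csv(
        path, index=False
    )
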
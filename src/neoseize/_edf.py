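"""Minimal EDF (European Data Format) writer.

EDF stores a fixed ASCII header followed by little-endian int16 data
records; each signal is linearly mapped between its physical and digital
ranges.  Only continuous, equal-rate, whole-second recordings are
supported, which is all this package produces.  Reading goes through
:func:`mne.io.read_raw_edf`.
"""

from __future__ import annotations

import datetime
from typing import Sequence

import numpy as np

_DIG_MIN = -32768
_DIG_MAX = 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} ascii chars")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int = 8) -> str:
    """Format a float into at most `width` ascii chars."""
    for fmt in (f"{x:.10g}", f"{x:.6g}", f"{x:.4g}", f"{x:.3g}", f"{x:.2g}"):
        if len(fmt) <= width:
            return fmt
    raise ValueError(f"cannot format {x} in {width} chars")


def write_edf(
    path,
    signals: Sequence[np.ndarray],
    labels: Sequence[str],
    units: Sequence[str],
    fs: float,
) -> None:
    """Write equal-length 1-D float arrays as an EDF file.

    The recording must span a whole number of seconds and ``fs`` must be
    an integer rate so that one-second data records tile it exactly.
    """
    if len(signals) == 0:
        raise ValueError("no signals to write")
    if not (len(signals) == len(labels) == len(units)):
        raise ValueError("signals, labels and units must have equal length")
    n = len(signals[0])
    if n == 0:
        raise ValueError("zero-length signals cannot be written to EDF")
    if any(len(s) != n for s in signals):
        raise ValueError("all signals must have equal length")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs_i = int(round(fs))
    if n % fs_i != 0:
        raise ValueError(
            f"recording length {n} is not a whole number of seconds at {fs_i} Hz; "
            "trim the recording or use CSV"
        )
    n_records = n // fs_i
    ns = len(signals)

    # physical range per signal; degenerate (constant) signals get a unit pad
    pmins, pmaxs, scaled = [], [], []
    for sig in signals:
        arr = np.asarray(sig, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("signals must be finite")
        pmin, pmax = float(arr.min()), float(arr.max())
        if pmax - pmin < 1e-12:
            pmin, pmax = pmin - 1.0, pmax + 1.0
        gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        dig = np.round((arr - pmin) * gain + _DIG_MIN).astype("<i2")
        pmins.append(pmin)
        pmaxs.append(pmax)
        scaled.append(dig)

    now = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate 01-JAN-2000 X X X", 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 * (1 + ns)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(ns), 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(_field(lab, 16) for lab in labels),
            b"".join(_field("", 80) for _ in range(ns)),
            b"".join(_field(u, 8) for u in units),
            b"".join(_field(_fmt_float(p), 8) for p in pmins),
            b"".join(_field(_fmt_float(p), 8) for p in pmaxs),
            b"".join(_field(str(_DIG_MIN), 8) for _ in range(ns)),
            b"".join(_field(str(_DIG_MAX), 8) for _ in range(ns)),
            b"".join(_field("", 80) for _ in range(ns)),
            b"".join(_field(str(fs_i), 8) for _ in range(ns)),
            b"".join(_field("", 32) for _ in range(ns)),
        ]
    )

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for rec in range(n_records):
            sl = slice(rec * fs_i, (rec + 1) * fs_i)
            for dig in scaled:
                fh.write(dig[sl].tobytes())
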
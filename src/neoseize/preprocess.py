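"""Modality-specific signal conditioning.

ECG: 5–15 Hz band-pass (suppresses powerline, EMG and baseline wander
while keeping QRS energy), Hamilton–Tompkins R-peak detection, and
RR-interval construction.  Respiration: global linear detrend plus a
60 s sliding-mean baseline correction, then breath-onset detection by
zero crossings.  Acceleration: 47 Hz low-pass, decimation by 2, 0.2 Hz
high-pass, then the Euclidean net magnitude.

All filters are 4th-order Butterworth applied forward–backward
(zero-phase), so detected peak positions are not shifted by filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import Signal, TriaxialSignal


@dataclass
class PeakIndices:
    """Strictly increasing sample positions of detected R peaks."""

    indices: np.ndarray
    fs: float

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.fs

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class RRSeries:
    """Successive R-to-R intervals in seconds."""

    intervals_s: np.ndarray

    def __post_init__(self):
        self.intervals_s = np.asarray(self.intervals_s, dtype=float)
        if self.intervals_s.size and np.any(self.intervals_s <= 0):
            raise ValueError("RR intervals must be positive")

    def __len__(self) -> int:
        return len(self.intervals_s)


@dataclass
class BreathOnsets:
    """Inhale / exhale onset times in seconds (upward / downward crossings)."""

    inhale_onsets_s: np.ndarray
    exhale_onsets_s: np.ndarray

    def __post_init__(self):
        self.inhale_onsets_s = np.asarray(self.inhale_onsets_s, dtype=float)
        self.exhale_onsets_s = np.asarray(self.exhale_onsets_s, dtype=float)
        for arr in (self.inhale_onsets_s, self.exhale_onsets_s):
            if arr.size and np.any(np.diff(arr) <= 0):
                raise ValueError("onset times must be strictly increasing")


def _butter_sos(order: int, Wn, btype: str, fs: float):
    return sps.butter(order, Wn, btype=btype, fs=fs, output="sos")


def _filtfilt(sos, x: np.ndarray) -> np.ndarray:
    return sps.sosfiltfilt(sos, x)


# ---------------------------------------------------------------------------
# ECG


def bandpass_ecg(sig: Signal, low_hz: float = 5.0, high_hz: float = 15.0, order: int = 4) -> Signal:
    """Zero-phase 5–15 Hz Butterworth band-pass of the raw ECG."""
    if sig.fs < 100.0:
        raise ValueError(f"ECG sampling rate {sig.fs} Hz too low for a {high_hz} Hz band")
    sos = _butter_sos(order, (low_hz, high_hz), "bandpass", sig.fs)
    return Signal(_filtfilt(sos, sig.samples), sig.fs, sig.label, sig.start_time)


def detect_r_peaks(
    sig: Signal,
    prefiltered: bool = False,
    threshold_coeff: float = 0.3125,
    refractory_s: float = 0.2,
    searchback_factor: float = 1.66,
) -> PeakIndices:
    """Hamilton–Tompkins R-peak detection.

    Stages: band-limit (5–15 Hz unless ``prefiltered``), differentiate,
    rectify, 80 ms moving-window integrate, then adaptive dual-threshold
    peak picking on local maxima of the integrated signal with a 200 ms
    refractory period and a search-back pass at ``searchback_factor`` times
    the running mean RR.  Detections are refined to the nearest maximum of
    the band-passed waveform, so reported indices sit on the R wave itself.
    """
    fs = sig.fs
    if len(sig.samples) < int(2 * fs):
        warnings.warn("signal shorter than detector warm-up; no peaks returned")
        return PeakIndices(np.empty(0, dtype=int), fs)
    filt = sig.samples if prefiltered else bandpass_ecg(sig).samples
    deriv = np.diff(filt, prepend=filt[0])
    rect = np.abs(deriv)
    win = max(1, int(round(0.08 * fs)))
    mwi = np.convolve(rect, np.ones(win) / win, mode="same")

    # candidate peaks: local maxima of the integrated signal
    cand, _ = sps.find_peaks(mwi, distance=max(1, int(round(refractory_s * fs / 2))))
    if cand.size == 0:
        return PeakIndices(np.empty(0, dtype=int), fs)

    warmup = mwi[: int(2 * fs)]
    spk = float(np.max(warmup))
    npk = float(np.mean(warmup))
    if spk <= 0:
        return PeakIndices(np.empty(0, dtype=int), fs)

    def threshold() -> float:
        return npk + threshold_coeff * (spk - npk)

    accepted: list[int] = []
    rr_hist: list[float] = []
    refractory = int(round(refractory_s * fs))
    missed_pool: list[int] = []  # sub-threshold candidates since last beat

    def accept(idx: int, peak_val: float):
        nonlocal spk
        spk = 0.125 * peak_val + 0.875 * spk
        if accepted:
            rr_hist.append((idx - accepted[-1]) / fs)
            del rr_hist[:-8]
        accepted.append(idx)
        missed_pool.clear()

    for idx in cand:
        val = mwi[idx]
        if accepted and idx - accepted[-1] < refractory:
            continue
        if val >= threshold():
            accept(idx, val)
        else:
            npk = 0.125 * val + 0.875 * npk
            missed_pool.append(idx)
        # search-back: a long RR gap suggests a missed low-amplitude beat
        if accepted and rr_hist:
            mean_rr = float(np.mean(rr_hist))
            if (idx - accepted[-1]) / fs > searchback_factor * mean_rr and missed_pool:
                pool = [j for j in missed_pool if j - accepted[-1] >= refractory]
                if pool:
                    best = max(pool, key=lambda j: mwi[j])
                    if mwi[best] >= 0.5 * threshold():
                        accept(best, mwi[best])

    if not accepted:
        return PeakIndices(np.empty(0, dtype=int), fs)

    # refine each detection to the nearest band-passed maximum
    half = int(round(0.1 * fs))
    refined = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(len(filt), idx + half + 1)
        refined.append(lo + int(np.argmax(filt[lo:hi])))
    refined = np.asarray(sorted(set(refined)), dtype=int)
    keep = np.concatenate(([True], np.diff(refined) >= refractory))
    return PeakIndices(refined[keep], fs)


def build_rr_series(peaks: PeakIndices) -> RRSeries:
    """RR intervals in seconds from consecutive peak indices."""
    if len(peaks) < 2:
        raise ValueError("insufficient beats: need at least 2 R peaks")
    return RRSeries(np.diff(peaks.indices) / peaks.fs)


# ---------------------------------------------------------------------------
# respiration


def detrend_respiration(sig: Signal, baseline_window_s: float = 60.0) -> Signal:
    """Remove global linear drift and a sliding-mean local baseline.

    The global component is the least-squares line through the data; the
    local baseline is a centred ``baseline_window_s`` moving average whose
    edge windows shrink rather than pad.  Recordings shorter than the
    baseline window fall back to the global detrend only.
    """
    x = sig.samples
    n = len(x)
    if n == 0:
        return Signal(x.copy(), sig.fs, sig.label, sig.start_time)
    t = np.arange(n) / sig.fs
    slope, intercept = np.polyfit(t, x, 1) if n > 1 else (0.0, x[0])
    y = x - (slope * t + intercept)
    win = int(round(baseline_window_s * sig.fs))
    if n < win:
        warnings.warn(
            f"respiration shorter than {baseline_window_s} s; global detrend only"
        )
        return Signal(y, sig.fs, sig.label, sig.start_time)
    baseline = (
        pd.Series(y).rolling(win, center=True, min_periods=1).mean().to_numpy()
    )
    return Signal(y - baseline, sig.fs, sig.label, sig.start_time)


def detect_breath_onsets(sig: Signal, refractory_s: float = 0.25) -> BreathOnsets:
    """Zero-crossing breath-onset detection on detrended respiration.

    Upward crossings mark inhale onsets, downward crossings exhale onsets.
    Zero samples attach to the preceding sign.  Crossings of either
    direction closer than ``refractory_s`` to the previously accepted
    crossing are suppressed as noise.
    """
    x = sig.samples
    if len(x) < 2:
        return BreathOnsets(np.empty(0), np.empty(0))
    s = np.sign(x)
    for i in range(1, len(s)):  # zeros inherit the preceding sign
        if s[i] == 0:
            s[i] = s[i - 1]
    cross = np.nonzero(s[1:] != s[:-1])[0] + 1
    cross = [i for i in cross if s[i] != 0]
    inhale, exhale = [], []
    last_t = -np.inf
    for i in cross:
        t = sig.start_time + i / sig.fs
        if t - last_t < refractory_s:
            continue
        (inhale if s[i] > 0 else exhale).append(t)
        last_t = t
    return BreathOnsets(np.asarray(inhale), np.asarray(exhale))


# ---------------------------------------------------------------------------
# acceleration


def preprocess_acceleration(
    acc: TriaxialSignal,
    lowpass_hz: float = 47.0,
    decim: int = 2,
    highpass_hz: float = 0.2,
) -> Signal:
    """Per-axis low-pass 47 Hz → decimate ×2 → high-pass 0.2 Hz; net magnitude.

    The 47 Hz low-pass doubles as the anti-alias stage for the decimation
    (output Nyquist 62.5 Hz at a 250 Hz input).  The returned net
    acceleration is the Euclidean magnitude of the three filtered axes and
    carries the decimated sampling rate.
    """
    fs_in = acc.fs
    if lowpass_hz >= fs_in / 2:
        raise ValueError(f"low-pass cut-off {lowpass_hz} Hz at or above Nyquist")
    fs_out = fs_in / decim
    sos_lp = _butter_sos(4, lowpass_hz, "lowpass", fs_in)
    sos_hp = _butter_sos(4, highpass_hz, "highpass", fs_out)
    filtered = []
    for ax in (acc.x, acc.y, acc.z):
        y = _filtfilt(sos_lp, ax.samples)[::decim]
        y = _filtfilt(sos_hp, y)
        filtered.append(y)
    net = np.sqrt(filtered[0] ** 2 + filtered[1] ** 2 + filtered[2] ** 2)
    return Signal(net, fs_out, "ACC_NET", acc.x.start_time)
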
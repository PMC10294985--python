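"""The 15-feature vector computed from each 5-minute epoch.

Ten features describe heart-rate variability from the RR-interval series
(time-domain statistics, Poincaré geometry, spectral band powers and the
RR range), four describe movement from the net wrist acceleration
(Welch band powers and the zero-crossing rate), and one is the breathing
rate from inhale onsets.  Canonical column order is ``FEATURE_NAMES``.

Conventions: population (divide-by-N) standard deviations throughout;
SD1 = SDSD/√2 and SD2 = √(2·SDNN² − SD1²), so 2·SDNN² = SD1² + SD2²
holds identically; CCM normalises the signed areas of consecutive
Poincaré-triple triangles by π·SD1·SD2 and the triangle count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .epoching import Epoch, merge_close_seizures, segment_and_label, slice_epoch
from .io import AnnotationSet, Recording, Signal
from .preprocess import (
    BreathOnsets,
    RRSeries,
    bandpass_ecg,
    build_rr_series,
    detect_breath_onsets,
    detect_r_peaks,
    detrend_respiration,
    preprocess_acceleration,
)

ECG_FEATURES = (
    "mean_rr_s",
    "sdnn_s",
    "sdsd_s",
    "pnn50_pct",
    "sd1_s",
    "sd2_s",
    "ccm",
    "lf_power",
    "hf_power",
    "rr_range_s",
)
ACC_FEATURES = ("acc_power_0_2", "acc_power_2_5", "acc_power_total", "acc_zcr")
RESP_FEATURES = ("resp_rate_bpm",)

#: canonical order of the 15 features
FEATURE_NAMES = ECG_FEATURES + ACC_FEATURES + RESP_FEATURES

#: feature subsets used by the three detector modes
MODE_FEATURES = {
    "full": FEATURE_NAMES,
    "ecg_only": ECG_FEATURES,
    "resp_acc": ACC_FEATURES + RESP_FEATURES,
}


class FeatureError(ValueError):
    """An epoch does not support the requested feature computation."""


# ---------------------------------------------------------------------------
# HRV


def hrv_time_features(rr: RRSeries) -> dict:
    """Mean RR, SDNN, SDSD, pNN50 (%) and RR range of one epoch."""
    x = rr.intervals_s
    if len(x) < 3:
        raise FeatureError("insufficient beats in epoch (need ≥ 3 RR intervals)")
    d = np.diff(x)
    return dict(
        mean_rr_s=float(np.mean(x)),
        sdnn_s=float(np.std(x)),
        sdsd_s=float(np.std(d)),
        pnn50_pct=float(100.0 * np.mean(np.abs(d) > 0.050)),
        rr_range_s=float(np.max(x) - np.min(x)),
    )


def poincare_features(rr: RRSeries) -> dict:
    """SD1, SD2 and the Complex Correlation Measure of the Poincaré plot.

    The plot scatters (RR_i, RR_{i+1}); SD1/SD2 are the dispersions across
    and along the identity line.  CCM sums the signed areas of triangles
    formed by consecutive point triples and normalises by π·SD1·SD2 and
    the triangle count, so it measures the *temporal* structure of the
    plot that SD1/SD2 ignore.  Degenerate (zero-variability) plots give 0.
    """
    x = rr.intervals_s
    if len(x) < 4:
        raise FeatureError("insufficient beats in epoch (need ≥ 4 RR intervals)")
    sdnn = np.std(x)
    sd1 = np.std(np.diff(x)) / np.sqrt(2.0)
    sd2 = np.sqrt(max(2.0 * sdnn**2 - sd1**2, 0.0))
    px, py = x[:-1], x[1:]  # M = len(x) - 1 points
    m = len(px)
    if sd1 * sd2 == 0.0 or m < 3:
        return dict(sd1_s=float(sd1), sd2_s=float(sd2), ccm=0.0)
    ax, ay = px[:-2], py[:-2]
    bx, by = px[1:-1], py[1:-1]
    cx, cy = px[2:], py[2:]
    areas = 0.5 * ((bx - ax) * (cy - ay) - (cx - ax) * (by - ay))
    ccm = float(np.sum(areas) / (np.pi * sd1 * sd2 * (m - 2)))
    return dict(sd1_s=float(sd1), sd2_s=float(sd2), ccm=ccm)


def hrv_spectral_features(
    rr: RRSeries,
    resample_hz: float = 4.0,
    segment_s: float = 60.0,
    lf_band: tuple = (0.04, 0.15),
    hf_band: tuple = (0.15, 1.0),
) -> dict:
    """LF and HF power (s²) of the heart-rate-variability spectrum.

    The tachogram (RR value at each beat time) is resampled to an even
    4 Hz grid by cubic interpolation, mean-removed, and analysed with
    averaged Hann-windowed periodograms (60 s segments, 50 % overlap).
    Band powers are trapezoidal integrals of the PSD.  The HF band runs
    to 1 Hz because neonatal breathing exceeds the adult 0.4 Hz bound.
    """
    x = rr.intervals_s
    t = np.cumsum(x)
    if len(x) < 4 or t[-1] - t[0] < 30.0:
        raise FeatureError("too few beats for spectral analysis (< 30 s of RR time)")
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    tach = interpolate.interp1d(t, x, kind="cubic")(grid)
    tach = tach - np.mean(tach)
    nperseg = min(int(segment_s * resample_hz), len(tach))
    f, psd = sps.welch(
        tach, fs=resample_hz, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant",
    )
    return dict(
        lf_power=_band_power(f, psd, lf_band),
        hf_power=_band_power(f, psd, hf_band),
    )


def _band_power(f: np.ndarray, psd: np.ndarray, band: tuple) -> float:
    m = (f >= band[0]) & (f <= band[1])
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[m], f[m]))


# ---------------------------------------------------------------------------
# respiration & movement


def respiration_rate(onsets: BreathOnsets) -> float:
    """Breaths/min as the reciprocal of the mean inhale-onset spacing."""
    t = onsets.inhale_onsets_s
    if len(t) < 2:
        raise FeatureError("no breathing detected (need ≥ 2 inhale onsets)")
    return float(60.0 / np.mean(np.diff(t)))


def zero_crossing_rate(x: np.ndarray, fs: float) -> float:
    """Strict sign changes per second of a mean-removed signal."""
    y = x - np.mean(x)
    s = np.sign(y)
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    changes = int(np.sum((s[1:] != s[:-1]) & (s[1:] != 0) & (s[:-1] != 0)))
    return changes / (len(x) / fs)


def acceleration_features(
    net: Signal,
    low_band: tuple = (0.0, 2.0),
    high_band: tuple = (2.0, 5.0),
    nperseg: int = 512,
) -> dict:
    """Welch band powers and zero-crossing rate of the net acceleration.

    The net magnitude is non-negative, so its mean is removed before both
    the spectrum and the ZCR (a magnitude cannot cross zero otherwise).
    Daily-activity energy sits mostly below 2 Hz whereas rhythmic seizure
    movement concentrates above it, hence the 0–2 / 2–5 Hz split.
    """
    x = net.samples - np.mean(net.samples)
    if len(x) < 2:
        raise FeatureError("net acceleration too short for spectral analysis")
    if len(x) < nperseg:
        warnings.warn("epoch shorter than one Welch segment; single periodogram used")
    seg = min(nperseg, len(x))
    f, psd = sps.welch(
        x, fs=net.fs, window="hann", nperseg=seg, noverlap=seg // 2,
        detrend="constant",
    )
    return dict(
        acc_power_0_2=_band_power(f, psd, low_band),
        acc_power_2_5=_band_power(f, psd, high_band),
        acc_power_total=_band_power(f, psd, (0.0, net.fs / 2)),
        acc_zcr=zero_crossing_rate(net.samples, net.fs),
    )


# ---------------------------------------------------------------------------
# epoch-level assembly


def extract_feature_vector(ecg: Signal, resp: Signal, acc) -> dict:
    """Run the full preprocessing + feature chain on one epoch's slices.

    Returns the 15 features keyed by ``FEATURE_NAMES``.  Raises
    :class:`FeatureError` if any modality cannot support its features
    (e.g. a flatline ECG yields no beats).
    """
    peaks = detect_r_peaks(bandpass_ecg(ecg), prefiltered=True)
    if len(peaks) < 2:
        raise FeatureError("no beats detected in epoch")
    rr = build_rr_series(peaks)
    vec: dict = {}
    vec.update(hrv_time_features(rr))
    vec.update(poincare_features(rr))
    vec.update(hrv_spectral_features(rr))
    vec.update(acceleration_features(preprocess_acceleration(acc)))
    onsets = detect_breath_onsets(detrend_respiration(resp))
    vec["resp_rate_bpm"] = respiration_rate(onsets)
    out = {name: vec[name] for name in FEATURE_NAMES}
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise FeatureError(f"non-finite features: {bad}")
    return out


@dataclass
class FailedEpoch:
    epoch: Epoch
    reason: str


def extract_features(
    rec: Recording,
    ann: AnnotationSet,
    gap_fill: bool = True,
) -> tuple[pd.DataFrame, list[FailedEpoch]]:
    """Feature matrix for one recording: merge → segment → extract per epoch.

    Returns one row per successfully processed epoch (15 feature columns
    plus ``subject_id``, ``epoch_start_s``, ``seizure_group_id``,
    ``label``) and the list of epochs dropped with their failure reason.
    """
    merged = merge_close_seizures(ann)
    epochs = segment_and_label(rec.duration_s, merged, rec.subject_id, gap_fill=gap_fill)
    rows, failed = [], []
    for ep in epochs:
        ecg, resp, acc = slice_epoch(rec, ep)
        try:
            vec = extract_feature_vector(ecg, resp, acc)
        except FeatureError as exc:
            failed.append(FailedEpoch(ep, str(exc)))
            continue
        rows.append(
            dict(
                subject_id=ep.subject_id,
                epoch_start_s=ep.start_s,
                seizure_group_id=ep.seizure_group_id,
                label=ep.label,
                **vec,
            )
        )
    cols = ["subject_id", "epoch_start_s", "seizure_group_id", "label", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols), failed


class FeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer: (Recording, AnnotationSet) pairs → feature table.

    ``transform`` maps a list of pairs to the concatenated feature matrix.
    Fitting is a no-op (the extraction chain has no trainable state); the
    class exists so the extraction step composes with sklearn pipelines
    and carries its parameters through ``get_params``/``set_params``.
    """

    def __init__(self, gap_fill: bool = True):
        self.gap_fill = gap_fill

    def fit(self, X, y=None):
        self.n_failed_ = 0
        return self

    def transform(self, X) -> pd.DataFrame:
        frames = []
        n_failed = 0
        for rec, ann in X:
            df, failed = extract_features(rec, ann, gap_fill=self.gap_fill)
            frames.append(df)
            n_failed += len(failed)
        self.n_failed_ = n_failed
        if not frames:
            return pd.DataFrame(
                columns=["subject_id", "epoch_start_s", "seizure_group_id", "label", *FEATURE_NAMES]
            )
        return pd.concat(frames, ignore_index=True)
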
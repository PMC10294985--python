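"""Synthetic multimodal recordings with seizure-locked signal changes.

Clinical recordings of neonatal seizures are privacy-restricted, so every
downstream stage of this package is exercised on simulated data that
reproduces the *statistical structure* the detector relies on:

* an RR-interval (beat-to-beat) process whose mean and variability shift
  during seizures — the default seizure signature is tachycardia with
  reduced variability;
* quasi-periodic respiration with a rate shift during seizures, plus the
  global linear drift and slow baseline wander that the preprocessing
  stage must remove;
* triaxial wrist acceleration with a gravity offset and a noise floor,
  and rhythmic seizure bursts whose energy sits above 2 Hz — the band
  separation the movement features exploit;
* ECG measurement artifacts: 50 Hz powerline interference, broadband EMG
  noise and baseline wander.

Every generator is deterministic given ``scenario.seed``; each channel
draws from its own substream so channels can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from .io import AnnotationSet, Recording, Signal, TriaxialSignal

# substream tags: one independent RNG stream per channel
_STREAM_RR, _STREAM_ECG, _STREAM_RESP, _STREAM_ACC = 0, 1, 2, 3


@dataclass
class SimulationScenario:
    """Parameters of one simulated recording.

    Durations and times are seconds, heart rate beats/min, respiration
    breaths/min, acceleration in g.  The seizure deltas are applied inside
    every ``seizure_schedule`` interval; setting them (and the movement
    burst amplitude) to zero simulates an asymptomatic seizure.
    """

    duration_s: float = 3600.0
    seizure_schedule: list = field(default_factory=list)
    fs_hz: float = 250.0
    seed: int = 0

    # cardiac
    baseline_hr_bpm: float = 140.0
    seizure_hr_delta_bpm: float = 25.0
    rr_sdnn_s: float = 0.02
    seizure_rr_sdnn_scale: float = 0.5
    rr_modulation_freq_hz: float = 0.4
    rr_modulation_depth_s: float = 0.01
    hr_drift_amp_bpm: float = 6.0
    hr_drift_period_s: float = 1200.0
    ecg_qrs_amp_mv: float = 1.0

    # respiration
    baseline_resp_rate_bpm: float = 40.0
    seizure_resp_delta_bpm: float = 15.0
    resp_rate_drift_amp_bpm: float = 4.0
    resp_rate_drift_period_s: float = 900.0
    resp_drift_slope_per_s: float = 0.002
    resp_wander_amp: float = 0.15
    resp_wander_freq_hz: float = 0.01
    resp_noise_sd: float = 0.03

    # movement
    movement_band_hz: tuple = (2.0, 5.0)
    movement_burst_amp_g: float = 0.3
    movement_burst_duty: float = 0.7
    baseline_motion_g: float = 0.02
    # ordinary (non-seizure) infant movement: sporadic bursts below 2 Hz
    normal_motion_rate_per_hour: float = 8.0
    normal_motion_amp_g: float = 0.15
    normal_motion_band_hz: tuple = (0.3, 2.0)
    normal_motion_dur_s: tuple = (5.0, 30.0)

    # ECG artifacts
    powerline_50hz_amp: float = 0.1
    emg_noise_sd: float = 0.05
    ecg_baseline_wander_amp: float = 0.2
    ecg_baseline_wander_freq_hz: float = 0.33

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")
        for hr in (
            self.baseline_hr_bpm - self.hr_drift_amp_bpm,
            self.baseline_hr_bpm - self.hr_drift_amp_bpm + self.seizure_hr_delta_bpm,
        ):
            if hr <= 0:
                raise ValueError(f"heart rate must stay > 0 bpm, got {hr}")
        for r in (
            self.baseline_resp_rate_bpm - self.resp_rate_drift_amp_bpm,
            self.baseline_resp_rate_bpm - self.resp_rate_drift_amp_bpm
            + self.seizure_resp_delta_bpm,
        ):
            if r <= 0:
                raise ValueError(f"respiration rate must stay > 0 bpm, got {r}")
        for name in (
            "rr_sdnn_s", "rr_modulation_depth_s", "movement_burst_amp_g",
            "baseline_motion_g", "powerline_50hz_amp", "emg_noise_sd",
            "ecg_baseline_wander_amp", "resp_wander_amp", "resp_noise_sd",
            "hr_drift_amp_bpm", "resp_rate_drift_amp_bpm",
            "normal_motion_rate_per_hour", "normal_motion_amp_g",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        sched = [(float(a), float(b)) for a, b in self.seizure_schedule]
        for a, b in sched:
            if not (0 <= a < b <= self.duration_s):
                raise ValueError(
                    f"seizure interval ({a}, {b}) not within [0, {self.duration_s}]"
                )
        if any(sched[i + 1][0] < sched[i][1] for i in range(len(sched) - 1)):
            raise ValueError("seizure_schedule intervals must be sorted and disjoint")
        self.seizure_schedule = sched

    def in_seizure(self, t: float) -> bool:
        return any(a <= t < b for a, b in self.seizure_schedule)

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationScenario":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        d = dict(d)
        if "movement_band_hz" in d:
            d["movement_band_hz"] = tuple(d["movement_band_hz"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationScenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["movement_band_hz"] = list(d["movement_band_hz"])
        d["seizure_schedule"] = [list(iv) for iv in d["seizure_schedule"]]
        return d


# ---------------------------------------------------------------------------
# cardiac chain


def generate_rr_process(scn: SimulationScenario) -> np.ndarray:
    """Generate strictly increasing R-peak times over the scenario duration.

    Each interval is the regime mean (60 / heart rate, seizure delta applied
    inside seizure intervals) plus a sinusoidal respiratory-sinus-type
    modulation and a Gaussian perturbation whose SD is ``rr_sdnn_s``
    (scaled by ``seizure_rr_sdnn_scale`` during seizures).
    """
    rng = scn._rng(_STREAM_RR)
    drift_phase = rng.uniform(0, 2 * np.pi)
    beats = []
    t = 0.0
    floor = 0.2  # physiological floor, 300 bpm
    while True:
        hr = scn.baseline_hr_bpm
        if scn.hr_drift_amp_bpm > 0:
            hr += scn.hr_drift_amp_bpm * np.sin(
                2 * np.pi * t / scn.hr_drift_period_s + drift_phase
            )
        if scn.in_seizure(t):
            mean_rr = 60.0 / (hr + scn.seizure_hr_delta_bpm)
            sd = scn.rr_sdnn_s * scn.seizure_rr_sdnn_scale
        else:
            mean_rr = 60.0 / hr
            sd = scn.rr_sdnn_s
        rr = (
            mean_rr
            + scn.rr_modulation_depth_s * np.sin(2 * np.pi * scn.rr_modulation_freq_hz * t)
            + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        )
        rr = max(rr, floor)
        if t + rr >= scn.duration_s:
            break
        t += rr
        beats.append(t)
    return np.asarray(beats)


def _qrs_template(fs: float, amp: float) -> np.ndarray:
    """Raised-cosine spike of ~80 ms width peaking at its centre."""
    half = int(round(0.04 * fs))
    n = 2 * half + 1
    return amp * 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / (n - 1)))


def synthesize_ecg(beat_times: Sequence[float], scn: SimulationScenario) -> Signal:
    """ECG-like waveform: a QRS template at each beat plus artifacts.

    The R-peak ground truth is ``beat_times`` itself — additive noise never
    moves it.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and (np.any(np.diff(beat_times) <= 0) or beat_times[-1] >= scn.duration_s):
        raise ValueError("beat times must be strictly increasing and within duration")
    fs = scn.fs_hz
    n = int(round(scn.duration_s * fs))
    x = np.zeros(n)
    tpl = _qrs_template(fs, scn.ecg_qrs_amp_mv)
    half = (len(tpl) - 1) // 2
    for bt in beat_times:
        c = int(round(bt * fs))
        lo, hi = c - half, c + half + 1
        tlo, thi = max(0, -lo), len(tpl) - max(0, hi - n)
        x[max(0, lo) : min(n, hi)] += tpl[tlo:thi]
    t = np.arange(n) / fs
    rng = scn._rng(_STREAM_ECG)
    if scn.powerline_50hz_amp > 0:
        x += scn.powerline_50hz_amp * np.sin(2 * np.pi * 50.0 * t)
    if scn.ecg_baseline_wander_amp > 0:
        x += scn.ecg_baseline_wander_amp * np.sin(
            2 * np.pi * scn.ecg_baseline_wander_freq_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if scn.emg_noise_sd > 0:
        x += rng.normal(0.0, scn.emg_noise_sd, n)
    return Signal(x, fs, "ECG")


# ---------------------------------------------------------------------------
# respiration


def _resp_rate_profile(scn: SimulationScenario, t: np.ndarray) -> np.ndarray:
    rate = np.full(t.shape, scn.baseline_resp_rate_bpm)
    for a, b in scn.seizure_schedule:
        rate[(t >= a) & (t < b)] += scn.seizure_resp_delta_bpm
    return rate


def synthesize_respiration(scn: SimulationScenario) -> tuple[Signal, np.ndarray]:
    """Respiration channel and its ground-truth inhale-onset times.

    The clean component is a unit sinusoid at the instantaneous breathing
    rate; inhale onsets are its upward zero-crossings (phase = 2πk, k ≥ 1).
    Drift, slow wander and white noise are added on top.
    """
    fs = scn.fs_hz
    n = int(round(scn.duration_s * fs))
    t = np.arange(n) / fs
    rng = scn._rng(_STREAM_RESP)
    rate = _resp_rate_profile(scn, t)
    if scn.resp_rate_drift_amp_bpm > 0:
        rate = rate + scn.resp_rate_drift_amp_bpm * np.sin(
            2 * np.pi * t / scn.resp_rate_drift_period_s + rng.uniform(0, 2 * np.pi)
        )
    phase = 2 * np.pi * np.cumsum(rate / 60.0) / fs
    clean = np.sin(phase)
    # ground truth: phase crossings of 2πk, linearly interpolated
    k = np.arange(1, int(phase[-1] / (2 * np.pi)) + 1)
    onsets = np.interp(2 * np.pi * k, phase, t)
    x = (
        clean
        + scn.resp_drift_slope_per_s * t
        + scn.resp_wander_amp
        * np.sin(2 * np.pi * scn.resp_wander_freq_hz * t + rng.uniform(0, 2 * np.pi))
    )
    if scn.resp_noise_sd > 0:
        x = x + rng.normal(0.0, scn.resp_noise_sd, n)
    return Signal(x, fs, "RESP"), onsets


# ---------------------------------------------------------------------------
# movement


def _burst_envelope(t_rel: np.ndarray, duty: float) -> np.ndarray:
    """On/off envelope with 1 s period, `duty` fraction on, 0.1 s cosine ramps."""
    period, ramp = 1.0, 0.1
    on = duty * period
    ph = np.mod(t_rel, period)
    env = np.zeros_like(ph)
    env[ph < on] = 1.0
    rising = ph < ramp
    env[rising] = 0.5 * (1 - np.cos(np.pi * ph[rising] / ramp))
    falling = (ph >= on - ramp) & (ph < on)
    env[falling] = 0.5 * (1 + np.cos(np.pi * (ph[falling] - (on - ramp)) / ramp))
    return env


def synthesize_acceleration(scn: SimulationScenario) -> TriaxialSignal:
    """Triaxial wrist acceleration: gravity on z, a white noise floor, and
    during each seizure a rhythmic burst whose frequency lies inside
    ``movement_band_hz`` (energy above 2 Hz, unlike ordinary infant motion).
    """
    fs = scn.fs_hz
    n = int(round(scn.duration_s * fs))
    t = np.arange(n) / fs
    rng = scn._rng(_STREAM_ACC)
    lo, hi = scn.movement_band_hz
    bursts = [
        (a, b, rng.uniform(lo, hi), rng.uniform(0, 2 * np.pi, size=3))
        for a, b in scn.seizure_schedule
    ]
    # sporadic ordinary movement (below 2 Hz), anywhere in the recording
    normal_events = []
    if scn.normal_motion_rate_per_hour > 0 and scn.normal_motion_amp_g > 0:
        n_events = rng.poisson(scn.normal_motion_rate_per_hour * scn.duration_s / 3600.0)
        nlo, nhi = scn.normal_motion_band_hz
        dlo, dhi = scn.normal_motion_dur_s
        for _ in range(n_events):
            a = rng.uniform(0.0, scn.duration_s)
            normal_events.append(
                (
                    a,
                    min(a + rng.uniform(dlo, dhi), scn.duration_s),
                    rng.uniform(nlo, nhi),
                    rng.uniform(0, 2 * np.pi, size=3),
                    scn.normal_motion_amp_g * rng.uniform(0.5, 1.5),
                )
            )
    axes = []
    for ax in range(3):
        x = rng.normal(0.0, scn.baseline_motion_g, n) if scn.baseline_motion_g > 0 else np.zeros(n)
        if ax == 2:
            x = x + 1.0  # gravity
        if scn.movement_burst_amp_g > 0:
            for a, b, f0, phases in bursts:
                m = (t >= a) & (t < b)
                tr = t[m] - a
                x[m] += (
                    scn.movement_burst_amp_g
                    * _burst_envelope(tr, scn.movement_burst_duty)
                    * np.sin(2 * np.pi * f0 * tr + phases[ax])
                )
        for a, b, f0, phases, amp in normal_events:
            m = (t >= a) & (t < b)
            tr = t[m] - a
            ramp = np.minimum(1.0, np.minimum(tr, (b - a) - tr) / 1.0)  # 1 s ramps
            x[m] += amp * np.clip(ramp, 0.0, 1.0) * np.sin(2 * np.pi * f0 * tr + phases[ax])
        axes.append(Signal(x, fs, f"ACC_{'XYZ'[ax]}"))
    return TriaxialSignal(*axes)


# ---------------------------------------------------------------------------
# assembly


def generate_recording(
    scn: SimulationScenario, subject_id: str = "sim"
) -> tuple[Recording, AnnotationSet]:
    """Generate all channels of one scenario, synchronized at ``fs_hz``."""
    beats = generate_rr_process(scn)
    ecg = synthesize_ecg(beats, scn)
    resp, _ = synthesize_respiration(scn)
    acc = synthesize_acceleration(scn)
    rec = Recording(subject_id, ecg, resp, acc)
    ann = AnnotationSet(list(scn.seizure_schedule))
    return rec, ann


def generate_cohort(
    n_subjects: int = 4,
    seizures_per_subject: int = 2,
    duration_s: float = 6000.0,
    seed: int = 0,
    **overrides,
) -> list[tuple[Recording, AnnotationSet]]:
    """Simulate a cohort with between-subject physiological variation.

    Baseline heart and breathing rates vary across subjects; seizures are
    placed with full 25 min pre / 20 min post context so the peri-seizure
    labeling scheme yields its nominal epoch counts.  Seizure timing is
    drawn from the subject's substream; all other parameters come from
    :class:`SimulationScenario` defaults unless overridden.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    out = []
    for s in range(n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 100 + s]))
        onset0 = rng.uniform(1500.0, 1700.0)
        schedule = []
        onset = onset0
        for _ in range(seizures_per_subject):
            dur = rng.uniform(60.0, 120.0)
            if onset + dur + 1200.0 > duration_s:
                break
            schedule.append((round(onset, 1), round(onset + dur, 1)))
            onset = onset + dur + rng.uniform(2800.0, 3000.0)
        params = dict(
            duration_s=duration_s,
            seizure_schedule=schedule,
            seed=int(seed) * 1000 + s,
            baseline_hr_bpm=float(rng.uniform(125.0, 160.0)),
            baseline_resp_rate_bpm=float(rng.uniform(35.0, 50.0)),
            # seizures express with subject-dependent strength in each modality
            seizure_hr_delta_bpm=float(25.0 * rng.uniform(0.6, 1.2)),
            seizure_resp_delta_bpm=float(15.0 * rng.uniform(0.6, 1.2)),
            movement_burst_amp_g=float(0.3 * rng.uniform(0.5, 1.3)),
        )
        params.update(overrides)
        scn = SimulationScenario(**params)
        out.append(generate_recording(scn, subject_id=f"S{s + 1:02d}"))
    return out
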
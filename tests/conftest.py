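import numpy as np
import pytest

from neoseize import SimulationScenario, generate_recording
from neoseize.simulate import generate_rr_process, synthesize_ecg


@pytest.fixture(scope="session")
def clean_scenario():
    """Artifact-free scenario: deterministic signal content only."""
    return SimulationScenario(
        duration_s=300.0,
        baseline_hr_bpm=120.0,
        rr_sdnn_s=0.0,
        rr_modulation_depth_s=0.0,
        hr_drift_amp_bpm=0.0,
        resp_rate_drift_amp_bpm=0.0,
        resp_noise_sd=0.0,
        resp_wander_amp=0.0,
        resp_drift_slope_per_s=0.0,
        powerline_50hz_amp=0.0,
        emg_noise_sd=0.0,
        ecg_baseline_wander_amp=0.0,
        baseline_motion_g=0.0,
        normal_motion_rate_per_hour=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def seizure_recording():
    """One-hour recording with a single isolated seizure at 1800 s."""
    scn = SimulationScenario(duration_s=3600.0, seizure_schedule=[(1800.0, 1890.0)], seed=7)
    return generate_recording(scn, subject_id="P1")


@pytest.fixture(scope="session")
def clean_ecg_and_beats():
    """Artifact-free 300 s ECG at 120 bpm with its ground-truth beat times."""
    scn = SimulationScenario(
        duration_s=300.0,
        baseline_hr_bpm=120.0,
        hr_drift_amp_bpm=0.0,
        powerline_50hz_amp=0.0,
        emg_noise_sd=0.0,
        ecg_baseline_wander_amp=0.0,
        seed=11,
    )
    beats = generate_rr_process(scn)
    return synthesize_ecg(beats, scn), beats


def match_events(detected, truth, tol_s):
    """Greedy one-to-one matching of event times; returns (tp, precision, recall)."""
    detected = np.asarray(detected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    used = np.zeros(len(detected), dtype=bool)
    tp = 0
    for t in truth:
        if len(detected) == 0:
            break
        d = np.abs(detected - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_s:
            tp += 1
            used[j] = True
    precision = tp / len(detected) if len(detected) else 0.0
    recall = tp / len(truth) if len(truth) else 0.0
    return tp, precision, recall
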
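import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neoseize import SimulationScenario
from neoseize.epoching import segment_and_label, slice_epoch
from neoseize.features import (
    ACC_FEATURES,
    ECG_FEATURES,
    FEATURE_NAMES,
    FeatureError,
    acceleration_features,
    extract_feature_vector,
    extract_features,
    hrv_spectral_features,
    hrv_time_features,
    poincare_features,
    respiration_rate,
    zero_crossing_rate,
)
from neoseize.io import Signal
from neoseize.preprocess import BreathOnsets, RRSeries


rr_arrays = st.lists(
    st.floats(min_value=0.3, max_value=1.2), min_size=6, max_size=60
).map(lambda v: np.asarray(v))


class TestHRVTimeFeatures:
    def test_constant_series_all_zero(self):
        f = hrv_time_features(RRSeries([0.5, 0.5, 0.5]))
        assert f["mean_rr_s"] == 0.5
        assert f["sdnn_s"] == f["sdsd_s"] == f["pnn50_pct"] == f["rr_range_s"] == 0.0

    def test_alternating_series_arithmetic(self):
        f = hrv_time_features(RRSeries([0.4, 0.6, 0.4]))
        assert abs(f["mean_rr_s"] - 0.46667) < 1e-4
        assert abs(f["sdnn_s"] - 0.09428) < 1e-4
        assert f["rr_range_s"] == pytest.approx(0.2)
        assert f["pnn50_pct"] == 100.0  # successive diffs of ±200 ms

    def test_pnn50_threshold_is_strict(self):
        # 40 ms successive differences sit below the 50 ms threshold
        f = hrv_time_features(RRSeries([0.5, 0.54, 0.5]))
        assert f["pnn50_pct"] == 0.0

    def test_too_few_intervals(self):
        with pytest.raises(FeatureError, match="insufficient"):
            hrv_time_features(RRSeries([0.5, 0.5]))


class TestPoincareFeatures:
    def test_constant_series_degenerate(self):
        f = poincare_features(RRSeries([0.5] * 10))
        assert f["sd1_s"] == f["sd2_s"] == f["ccm"] == 0.0

    def test_sd1_sd2_match_rotation_oracle(self):
        """SD1/SD2 agree with standard deviations in 45°-rotated coordinates."""
        rng = np.random.default_rng(0)
        x = 0.5 + 0.05 * rng.standard_normal(50)
        f = poincare_features(RRSeries(x))
        p, q = x[:-1], x[1:]
        u = (q - p) / np.sqrt(2)  # across the identity line
        v = (q + p) / np.sqrt(2)  # along the identity line
        assert f["sd1_s"] == pytest.approx(np.std(u), abs=1e-12)
        # SD2 from the 2·SDNN² identity differs from the rotated std only by
        # O(1/N) edge terms of the lagged series
        assert f["sd2_s"] == pytest.approx(np.std(v), rel=0.05)

    def test_ccm_matches_shoelace_oracle(self):
        rng = np.random.default_rng(3)
        rr = 0.5 + 0.02 * np.cumsum(rng.standard_normal(12)) * 0.3 \
            + 0.03 * rng.standard_normal(12)
        f = poincare_features(RRSeries(rr))
        pts = list(zip(rr[:-1], rr[1:]))
        total = 0.0
        for (x1, y1), (x2, y2), (x3, y3) in zip(pts, pts[1:], pts[2:]):
            total += 0.5 * np.linalg.det([[x2 - x1, y2 - y1], [x3 - x1, y3 - y1]])
        sdnn = np.std(rr)
        sd1 = np.std(np.diff(rr)) / np.sqrt(2)
        sd2 = np.sqrt(2 * sdnn**2 - sd1**2)
        expected = total / (np.pi * sd1 * sd2 * (len(pts) - 2))
        assert f["ccm"] == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(rr=rr_arrays)
    def test_sd_identities_hold_for_any_series(self, rr):
        """SD1 = SDSD/√2 always; 2·SDNN² = SD1² + SD2² unless SD2 clips at 0."""
        f = poincare_features(RRSeries(rr))
        t = hrv_time_features(RRSeries(rr))
        assert f["sd1_s"] == pytest.approx(t["sdsd_s"] / np.sqrt(2), abs=1e-12)
        if 2 * t["sdnn_s"] ** 2 >= f["sd1_s"] ** 2:
            assert 2 * t["sdnn_s"] ** 2 == pytest.approx(
                f["sd1_s"] ** 2 + f["sd2_s"] ** 2, abs=1e-12
            )
        else:  # strongly alternating series: the major axis collapses
            assert f["sd2_s"] == 0.0


class TestHRVSpectralFeatures:
    def test_constant_rr_no_power(self):
        f = hrv_spectral_features(RRSeries([0.5] * 200))
        assert f["lf_power"] < 1e-10 and f["hf_power"] < 1e-10

    @pytest.mark.parametrize(
        "mod_freq,dominant,other",
        [(0.1, "lf_power", "hf_power"), (0.4, "hf_power", "lf_power")],
    )
    def test_single_tone_lands_in_its_band(self, mod_freq, dominant, other):
        t = np.cumsum(np.full(600, 0.5))
        rr = 0.5 + 0.05 * np.sin(2 * np.pi * mod_freq * t)
        f = hrv_spectral_features(RRSeries(rr))
        assert f[dominant] > 10 * f[other]

    def test_too_short_rejected(self):
        with pytest.raises(FeatureError):
            hrv_spectral_features(RRSeries([0.5] * 10))


class TestRespirationRate:
    @pytest.mark.parametrize("spacing,expected", [(2.0, 30.0), (4.0 / 3.0, 45.0)])
    def test_rate_from_onset_spacing(self, spacing, expected):
        onsets = BreathOnsets(np.arange(10) * spacing, np.empty(0))
        assert respiration_rate(onsets) == pytest.approx(expected)

    def test_single_onset_rejected(self):
        with pytest.raises(FeatureError, match="no breathing"):
            respiration_rate(BreathOnsets(np.array([1.0]), np.empty(0)))


class TestAccelerationFeatures:
    def test_all_zero_net(self):
        f = acceleration_features(Signal(np.zeros(4000), 125.0))
        assert all(f[k] == 0.0 for k in ACC_FEATURES)

    def test_constant_net_magnitude_has_no_features(self):
        # sin²+cos² = 1: a circular motion gives a constant magnitude
        t = np.arange(int(300 * 125)) / 125.0
        net = np.sqrt(np.sin(2 * np.pi * 3 * t) ** 2 + np.cos(2 * np.pi * 3 * t) ** 2)
        f = acceleration_features(Signal(net, 125.0))
        assert f["acc_power_total"] < 1e-10
        assert f["acc_zcr"] == 0.0

    def test_tone_concentrates_in_high_band_and_parseval(self):
        t = np.arange(int(300 * 125)) / 125.0
        rng = np.random.default_rng(1)
        x = 0.4 * np.sin(2 * np.pi * 3.0 * t) + rng.normal(0, 0.01, len(t))
        f = acceleration_features(Signal(x - x.min(), 125.0))
        assert f["acc_power_2_5"] / f["acc_power_total"] > 0.8
        assert f["acc_power_total"] == pytest.approx(np.var(x), rel=0.05)

    def test_spectral_features_invariant_to_offset(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.1, 8000)
        a = acceleration_features(Signal(x, 125.0))
        b = acceleration_features(Signal(x + 5.0, 125.0))
        for k in ACC_FEATURES:
            assert a[k] == pytest.approx(b[k], rel=1e-9)

    def test_zcr_counts_strict_sign_changes(self):
        # 1 Hz square wave over 10 s: 19 interior sign changes (the final
        # downward edge coincides with the end of the window)
        t = np.arange(1250) / 125.0
        x = np.sign(np.sin(2 * np.pi * 1.0 * t)) + 3.0  # offset removed internally
        assert zero_crossing_rate(x, 125.0) == pytest.approx(19 / 10.0)


class TestFeatureVectorAssembly:
    def test_epoch_yields_exactly_15_named_features(self, seizure_recording):
        rec, ann = seizure_recording
        ep = segment_and_label(rec.duration_s, ann, rec.subject_id)[0]
        vec = extract_feature_vector(*slice_epoch(rec, ep))
        assert tuple(vec.keys()) == FEATURE_NAMES
        assert len(vec) == 15
        assert len(ECG_FEATURES) == 10
        assert all(np.isfinite(v) for v in vec.values())

    def test_flatline_ecg_fails_cleanly(self, seizure_recording):
        rec, ann = seizure_recording
        ep = segment_and_label(rec.duration_s, ann, rec.subject_id)[0]
        ecg, resp, acc = slice_epoch(rec, ep)
        flat = Signal(np.zeros_like(ecg.samples), ecg.fs, "ECG")
        with pytest.raises(FeatureError):
            extract_feature_vector(flat, resp, acc)

    def test_extraction_is_deterministic(self, seizure_recording):
        rec, ann = seizure_recording
        ep = segment_and_label(rec.duration_s, ann, rec.subject_id)[0]
        a = extract_feature_vector(*slice_epoch(rec, ep))
        b = extract_feature_vector(*slice_epoch(rec, ep))
        assert a == b

    def test_recording_level_matrix_shape_and_labels(self, seizure_recording):
        rec, ann = seizure_recording
        df, failed = extract_features(rec, ann)
        assert list(df.columns[4:]) == list(FEATURE_NAMES)
        assert len(df) + len(failed) == 10
        assert (df["label"] == "seizure").sum() == 1
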
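# Methods

## Problem setting

The package detects neonatal seizures from three non-EEG wearable
channels sampled synchronously at 250 Hz: a chest ECG (mV), an
abdominal strain respiration channel (arbitrary units), and a triaxial
wrist accelerometer (g).  Detection is epoch-level: each 5-minute
window is classified seizure / non-seizure.  The pipeline cannot and
does not locate seizure onset within a window.

Times are seconds from recording start; seizure intervals are
half-open `[onset, offset)`.

## Preprocessing

All filters are 4th-order Butterworth applied forward–backward
(`scipy.signal.sosfiltfilt`), i.e. zero-phase, so filtering never
shifts peak positions — the property the R-peak and breath-onset
timings rely on.

**ECG.**  A 5–15 Hz band-pass suppresses the three dominant artifact
classes (50 Hz powerline, broadband EMG, sub-Hz baseline wander) while
retaining QRS energy.  R peaks are found with a Hamilton–Tompkins
detector: differentiate, rectify, 80 ms moving-window integration,
then adaptive dual-threshold peak picking with running signal/noise
peak estimates (threshold coefficient 0.3125, update weight 0.125), a
200 ms refractory period, and a search-back pass triggered when the
current gap exceeds 1.66× the running mean of the last 8 RR intervals.
Detections are refined to the nearest band-passed maximum within
±100 ms so indices land on the R wave.  All constants are keyword
arguments.  RR intervals are successive peak differences in seconds.

**Respiration.**  The global least-squares line is subtracted, then a
centred 60 s sliding-mean baseline whose edge windows shrink rather
than pad (no padded samples ever enter the output).  Inhale/exhale
onsets are upward/downward zero crossings with a 0.25 s refractory gap
— the shortest interval compatible with ~120 breaths/min, the upper
edge of plausible neonatal rates — to suppress noise chatter around
zero.

**Acceleration.**  Per axis: 47 Hz low-pass (also the anti-alias
stage), decimation by 2 to 125 Hz (Nyquist 62.5 Hz, so no further
anti-aliasing is needed), 0.2 Hz high-pass to remove gravity and
orientation drift.  The *net* acceleration is the Euclidean magnitude
of the three filtered axes.  Because a magnitude is non-negative, the
movement features subtract its mean before spectral analysis and
zero-crossing counting; without this, the zero-crossing rate of a
magnitude would be identically zero.

## Epoching and labeling

Non-seizure time dominates clinical monitoring by orders of magnitude,
so labeling is seizure-anchored rather than exhaustive.  Seizures
separated by less than 5 min are merged into one event.  Per merged
seizure: one seizure epoch `[onset, onset+300 s)`; up to five
non-seizure epochs tiling the 25 min before onset; up to four
non-seizure epochs tiling the 20 min after the seizure epoch (or after
the clinical offset when the seizure outlasts its epoch).  Epochs that
would cross the recording boundary or overlap an already-claimed
window are dropped, never padded or shifted.  An isolated seizure with
full context therefore yields 1 + 9 epochs = 50 labeled minutes — the
1:9 class balance the classifier is designed around.

For inter-seizure gaps between 5 and 45 min, an additional up-to-20 min
of non-seizure data is credited to the later seizure.  The pre- and
post-blocks already tile any such gap completely (25 + 20 = 45 min), so
the extra epochs walk backward from the later seizure's pre-block,
skipping claimed windows, until four are placed or the recording start
is reached.  This reproduces the bookkeeping in which a four-seizure
subject with two such gaps carries 240 rather than 200 labeled minutes.
The behaviour can be disabled (`gap_fill=False`).

## Features (15 per epoch)

HRV features use population (divide-by-N) standard deviations
throughout; the convention is fixed, not estimated per call.

| group | features |
|---|---|
| ECG (10) | mean RR, SDNN, SDSD, pNN50, SD1, SD2, CCM, LF power, HF power, RR range |
| movement (4) | band power 0–2 Hz, band power 2–5 Hz, total power, zero-crossing rate |
| respiration (1) | breathing rate (breaths/min) |

*Poincaré.*  SD1 = SDSD/√2; SD2 = √(2·SDNN² − SD1²) clipped at zero,
so 2·SDNN² = SD1² + SD2² holds identically off the clip.  CCM sums the
signed areas of triangles over consecutive Poincaré-point triples
(points (RR_i, RR_{i+1}), lag 1) and normalises by π·SD1·SD2·(M−2)
with M the number of points; degenerate plots return 0.

*HRV spectrum.*  The tachogram is resampled to an even 4 Hz grid by
cubic interpolation, mean-removed, and analysed by averaged
Hann-windowed periodograms (60 s segments, 50 % overlap).  LF is the
trapezoidal band integral over 0.04–0.15 Hz.  HF runs 0.15–1.0 Hz
rather than the adult 0.15–0.4 Hz because neonatal breathing commonly
exceeds 0.4 Hz; both edges are configurable.  Powers are absolute
(s²), not normalised.

*RR range* (max − min) is the tenth ECG feature; where a summary of
"the RR-interval signal" is ambiguous, the range is the simplest
dispersion not already covered by SDNN.

*Movement.*  Welch PSD (512-sample segments at 125 Hz, 50 % overlap,
Hann); band powers by trapezoidal integration; epochs shorter than one
segment fall back to a single periodogram with a warning.  Total power
over the full band matches the time-domain variance (Parseval) within
5 % for stationary inputs — an invariant under test.  ZCR counts
strict sign changes of the mean-removed net signal per second; zero
samples inherit the preceding sign.

Epochs whose slices cannot support a feature (flatline ECG, fewer than
4 RR intervals, fewer than 2 inhale onsets) are dropped with a recorded
reason and counted in the run log, never silently imputed.

## Classifier and evaluation

`SeizureClassifier` is a scikit-learn estimator: an optional
`StandardScaler` fitted on training data only (the features mix
seconds, s², g² and breaths/min — an RBF kernel needs commensurate
scales) followed by `SVC(kernel="rbf")`.  Defaults `C=1`,
`gamma="scale"`, no class weighting: the SVM's margin construction
handles the moderate 1:9 imbalance without modification.

Cross-validation is leave-one-patient-out; for a test patient with
several seizure events a double leave-one-seizure-out inner loop holds
out one event (its seizure epoch plus the non-seizure epochs anchored
to it) while the patient's remaining events join the training set.
Every epoch receives exactly one out-of-fold prediction; fold
disjointness is audited in the test suite.

Metrics: SEN = TP/(TP+FN), SPE = TN/(TN+FP), ACC, precision, recall,
F1 (reported as 0 with a flag when precision+recall = 0), FAH =
FP / monitored hours with monitored hours = evaluated epochs × 5 min,
and ROC AUC from the SVM decision scores (trapezoidal; equal to the
Mann–Whitney pair statistic, verified against exhaustive pair counting
in tests).  Pooling is across patients, not a per-patient average.
Three detector modes are compared: `full` (15 features), `ecg_only`
(10), `resp_acc` (5).

## Synthetic data

The simulator emulates the statistical structure the detector exploits,
not waveform realism:

* **RR process** — intervals drawn around the regime mean 60/HR with
  Gaussian SD `rr_sdnn_s` (default 20 ms) plus one sinusoidal
  respiratory-sinus-type modulation (0.4 Hz, 10 ms).  Baseline HR
  defaults to 140 bpm with a slow ±6 bpm sinusoidal drift (20 min
  period).  During seizures HR rises by +25 bpm and the Gaussian SD is
  halved — tachycardia with reduced variability, the typical neonatal
  autonomic signature.  All deltas are configurable, including zero
  (asymptomatic seizures).
* **ECG waveform** — an 80 ms raised-cosine spike (1 mV) at each beat;
  morphology beyond that is irrelevant to a band-pass + peak-picking
  chain and is not attempted.  Artifacts: 50 Hz powerline (0.1 mV),
  white EMG noise (0.05 mV SD), 0.33 Hz baseline wander (0.2 mV).
* **Respiration** — unit sinusoid at the instantaneous rate (40
  breaths/min baseline, ±4 slow drift, +15 during seizures) plus linear
  drift, slow wander and white noise; ground-truth inhale onsets are
  the phase's 2πk crossings.
* **Acceleration** — gravity on z, a 0.02 g noise floor, sporadic
  ordinary movement bursts (8/hour, 5–30 s, 0.3–2 Hz, ~0.15 g) anywhere
  in the recording, and during seizures an amplitude-modulated
  oscillation at a per-seizure frequency drawn from 2–5 Hz (0.3 g, 70 %
  duty) — the band separation the movement features rely on.

One seed drives independent per-channel substreams
(`numpy.random.SeedSequence([seed, channel])`), so channels are
individually reproducible.  The cohort generator varies baseline HR
(125–160 bpm), breathing rate (35–50), and per-subject seizure
expression strength (×0.6–1.2 cardiac/respiratory, ×0.5–1.3 movement)
across subjects.

What the simulator does *not* model — real QRS morphology and ectopy,
apnea, sensor detachment, movement-corrupted ECG, asymptomatic seizure
types — bounds what passing tests show: they validate the pipeline's
correctness and its ability to exploit multimodal seizure signatures,
not clinical performance on hospital data.

## Problem sizes and numerical choices

The evaluation cohort used in tests is 4 subjects × 100 min × 2
seizures (≈70–80 epochs), enough to exercise both cross-validation
loops and the three-mode comparison across 10 seeded replicates.
RR intervals are floored at 0.2 s; EDF export quantizes to 16 bits
over each channel's physical range and requires whole-second,
integer-rate recordings (use CSV otherwise); ties in ZCR and pNN50 are
resolved by strict inequalities; CSV sampling rates inferred from a
time column are rounded to 1 mHz.

## Known limitations

* Epoch-level decisions only; no onset-time localisation.
* No artifact-based epoch rejection or sleep/wake stratification.
* The RR spectrum is computed from detected (not ground-truth) beats;
  gross detector failure would corrupt LF/HF silently — mitigated by
  the detector's tested ≥0.99 F1 across 80–200 bpm.
* Synthetic validation only; clinical figures (e.g. sensitivity near
  40 % with FAH ≈ 0.5/h reported for comparable detectors on real
  cohorts) are not reproducible without restricted data.
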
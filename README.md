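# ppgshake

In-ear photoplethysmography (PPG) signal quality and vital-sign extraction
under helicopter-cabin vibration, with a synthetic cohort generator and the
full intra-subject agreement analysis.

## The problem

Pulse oximeters estimate pulse rate (PR) and oxygen saturation (SpO₂) from
the optical pulse wave. During helicopter transport the patient is exposed to
narrow-band whole-body vibration at rotor harmonics (here 23.5 Hz and
31.3 Hz), which superimposes high-frequency, low-amplitude artifacts on the
PPG. The question this package addresses in silico: do such artifacts degrade
standard PPG signal-quality indices (SQIs) or the vital signs extracted from
an in-ear two-wavelength sensor, relative to a clinical reference monitor?

Because no raw recordings of this kind are publicly available, the package
ships a first-class synthetic cohort generator that emulates the study
design: per subject, 10 min of seated rest (`no_flight`) and 10 min of
simulated cabin vibration (`in_flight`), each with two-channel PPG (red
655 nm / infrared 940 nm at 200 Hz), tri-axial seat acceleration (400 Hz)
and emulated reference vitals (1 Hz). Every stage of the analysis is then
verifiable against known ground truth.

## What it computes

**Seven SQIs** on sliding 5-s windows, resampled to 0.2 Hz:

- perfusion index `PI = 100 · A_AC / A_DC` (%)
- skewness `(1/N) Σ ((xᵢ − μ̂)/σ)³` and excess kurtosis
  `(1/N) Σ ((xᵢ − μ̂)/σ)⁴ − 3` (population moments)
- entropy `−Σ xᵢ² ln xᵢ²` of the centred, unit-energy window (nats)
- ratio of ratios `Ω = (A_AC,R/A_DC,R)/(A_AC,IR/A_DC,IR)`
- a 0–100 spectral-dominance quality indicator (QI)
- valid pulse detection (VPD): % of beats passing physiological and
  template-similarity checks

**Vital signs**: PR as the dominant spectral frequency of the trailing 8-s
infrared AC segment restricted to 0.5–3.67 Hz (30–220 bpm) with parabolic
peak interpolation; SpO₂ from the beat-wise median Ω through a linear
calibration `SpO₂ = a − b·Ω` (defaults a = 110, b = 25). The reference
monitor is emulated by its published rules (HR: mean of the last 10 R-R
intervals after dropping the two longest and two shortest; SpO₂: trailing
8-s mean).

**Statistics**: intra-subject phase comparison of per-subject SQI means with
a Shapiro–Wilk-gated paired t-test / Wilcoxon signed-rank test (exact p for
n ≤ 25 without ties); Bland–Altman bias and limits of agreement
(bias ± 1.96·SD of the paired differences); Lin's concordance correlation
coefficient `CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)` with McBride strength
categories; Welch spectra with artifact-peak detection.

## Worked example

Run the full in-silico study (16 subjects × 2 × 10 min, fixed master seed):

```sh
$ ppgshake run-study --out study_out
minimum SQI phase-comparison p-value: 0.099
pr no_flight: bias +0.02, CCC 0.996 (almost_perfect)
pr in_flight: bias -0.03, CCC 0.996 (almost_perfect)
spo2 no_flight: bias +1.42, CCC 0.449 (poor)
spo2 in_flight: bias +1.62, CCC 0.378 (poor)
report written to study_out/report.json
```

Reading: none of the eleven SQI phase comparisons is significant (all
p > 0.05), i.e. the low-amplitude rotor-harmonic artifact does not measurably
degrade signal quality. Pulse rate agrees almost perfectly with the reference
(CCC 0.996 in both phases) because the artifact frequencies lie far outside
the physiological search band. SpO₂ shows a positive bias of ≈ +1.4% against
the finger reference — the built-in ear-vs-finger site offset — which caps
its CCC at "poor" despite small random error, in both phases alike.

`study_out/tables/` holds the per-SQI normality, paired-test and agreement
tables as CSV; `report.json` carries the complete structured report,
reproducible bit-for-bit from the master seed.

The same library is scriptable directly:

```python
import ppgshake as ps

cohort = ps.CohortConfig(n_subjects=2, master_seed=0)
subject = ps.generate_cohort(cohort, ps.VibrationProfile())[0]
spec = ps.accel_spectrum(subject.accel["in_flight"])
print(ps.find_artifact_peaks(spec, fmin=10, n_peaks=2))
# [(23.5018..., 0.0264...), (31.2994..., 0.0122...)]
```

## Layout

- `src/ppgshake/types.py`, `io.py` — domain records, CSV schemas, the two
  trailing-window resamplers (0.2 Hz moving average; 30-s vitals sampling)
- `src/ppgshake/cohort.py` — synthetic cohort generator
- `src/ppgshake/sqi.py`, `vitals.py`, `filters.py` — SQI and vital-sign
  extraction
- `src/ppgshake/spectral.py` — Welch spectra, artifact peaks, phase
  comparison
- `src/ppgshake/stats.py` — paired tests, Bland–Altman, Lin's CCC
- `src/ppgshake/pipeline.py`, `cli.py` — study orchestration and the
  `ppgshake` command
- `docs/methods.md` — model, parameter and design documentation
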
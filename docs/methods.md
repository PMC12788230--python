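# Methods

This note documents the models, parameter choices and numerical conventions
behind `ppgshake`: what the synthetic cohort emulates, how each quantity is
computed, and where genuinely open design choices were resolved.

## Synthetic cohort model

### Subjects

Each virtual subject is drawn deterministically from `(master_seed, index)`:

| parameter | distribution | rationale |
|---|---|---|
| resting HR | Normal(70, 11) bpm, truncated [45, 110] | typical resting adult population |
| SpO₂ | Normal(96.5, 1.2) %, truncated [90, 100] | healthy normoxic range |
| perfusion index | log-normal, median 1.0 %, σ = 0.45 | ear-canal PPG perfusion is around 1 % with a right-skewed spread |
| DC level (IR) | log-normal, median 2.0 a.u. | arbitrary intensity units; red DC ≈ 0.95× IR |
| within-phase HR SD | ≈ 2 bpm (log-normal spread) | resting heart-rate variability |
| respiratory rate | Normal(0.25, 0.04) Hz, clipped [0.15, 0.40] | quiet breathing |
| white sensor noise | ≈ 0.12 % of DC per channel, independent | photodiode/electronics floor |
| perturbation noise | ≈ 0.26 % of DC, common-mode, band-limited 10–40 Hz | tissue/contact perturbations; see below |

The two noise components are deliberately distinct. A single white floor
cannot simultaneously produce the moderate spectral-dominance (QI) scores
seen on real in-ear recordings and the near-perfect pulse-band behaviour
(beat detection, PR, SpO₂) those same recordings support. Contact and
tissue perturbations in a sensor clamped in the ear canal are predominantly
broadband above the pulse band and are shared between the two wavelengths
(both LEDs interrogate the same tissue volume), hence a common-mode
10–40 Hz component scaled by each channel's DC, plus a small independent
white floor per channel.

### Cardiac rhythm

Inter-beat intervals follow a first-order autoregressive process
(φ = 0.85) with mean 60000/HR ms and stationary SD mapped from the bpm
variability; every interval is clipped to [300, 2000] ms. AR(1) gives the
short-range correlation of resting sinus rhythm without modelling
respiratory sinus arrhythmia explicitly.

### Pulse waveform

Each beat contributes two Gaussians: a systolic wave centred on the beat
time (width 0.13·IBI, unit amplitude) and a dicrotic wave at 45 % of the
IBI after it (width 0.15·IBI, amplitude 0.20). Widths scale with the local
IBI so slow and fast rhythms produce self-similar pulses. The widths and
dicrotic amplitude were chosen so the fundamental clearly dominates the
first harmonic in the spectrum — as in real PPG — which matters for both
the dominant-frequency PR estimator and the QI proxy. The summed train is
normalised so its median per-beat peak-to-trough equals the target
amplitude, `PI/100 · DC`.

Polarity: pulses are *subtracted* from the DC intensity (absorbance rises
with blood volume), so the raw channels carry downward pulses. Beat
detection and amplitude measurement operate on the inverted (pulse-up) AC
signal; the moment-based SQIs operate on the AC signal as emitted, which
fixes the sign convention of skewness.

The red channel shares the pulse shape; its AC/DC ratio is scaled so the
true ratio-of-ratios satisfies `Ω = (a − SpO₂)/b` under the cohort
calibration (defaults a = 110, b = 25). This linear curve is a conventional
stand-in for the proprietary device calibration; published device values of
Ω (~0.59) against SpO₂ (~97 %) imply a different curve, and no attempt is
made to force agreement.

Baseline: a 0.01 Hz drift sinusoid at 1 % of DC plus a respiratory
sinusoid at 0.5 % of DC, with seeded phases shared between channels.

### Vibration artifact

The in-flight phase adds, to both optical channels, one sinusoid per rotor
harmonic (defaults 23.5 Hz and 31.3 Hz) with amplitude
`rel_amplitude · A_AC` (default 0.10 — the artifact is a small fraction of
the pulsatile amplitude), amplitude-modulated at 0.1 Hz with depth 0.2 to
mimic flight-manoeuvre modulation. The accelerometer carries the same
harmonics around the 1 g gravity baseline (0.05 g and 0.03 g on the
vertical axis; lateral axes ×0.3 with independent phases; a scalar 0.7
damping at the head location reflects seat-to-head attenuation).

### Between-phase physiological state

Real repeated resting measurements of the same subject differ between
sessions: perfusion, noise conditions, heart rate and saturation all move
together with arousal and vasomotor state. A latent state `g ~ N(0,1)` per
(subject, phase) shifts HR by 2.5·g bpm, scales the pulsatile amplitude by
e^(0.12·g), scales both noise components by e^(−0.25·g) and shifts SpO₂ by
0.25·g %. Consequences: (i) phase differences of every SQI have mean zero
in the absence of vibration effects, (ii) the differences of the eleven
SQIs are strongly correlated, because they share one dominant source of
variance — as they do in real data, and (iii) per-subject phase means
differ by realistic amounts (e.g. PI by ~15 % relative). Couplings were
fixed from the magnitude of between-phase changes reported for this kind
of protocol, before any end-to-end testing.

### Reference monitor

Reference HR applies the monitor rule to the *true* beat series — mean of
the latest 10 R-R intervals after excluding the two longest and two
shortest — plus display jitter (SD 0.5 bpm). Reference SpO₂ is the true
value plus an ear-vs-finger site offset (default −1.0 %: the finger reads
lower than the ear canal) plus noise (SD 0.4 %), smoothed by the monitor's
trailing 8-s mean. The site offset is the dominant cause of the "poor"
SpO₂ concordance: a systematic offset between sites caps Lin's CCC however
small the random error.

## Extraction pipeline

**AC/DC split.** Zero-phase 4th-order Butterworth filters: low-pass 0.4 Hz
for DC, band-pass 0.5–10 Hz for AC. At 23.5 Hz the forward-backward
band-pass attenuates by ≈ 65 dB, so rotor harmonics are absent from every
beat-based quantity. Edge effects are confined to roughly one settling
length (a few seconds) at each end of a record.

**Beat detection.** Local maxima of the pulse-up AC with minimum
separation 0.3 s and prominence ≥ 0.4 × the trailing-10-s 90th percentile
of |AC| (adaptive, so detection survives amplitude changes). A
band-dominance gate rejects records whose variance is not majority
pulse-band (per-2-s-block median fraction below 8 Hz < 0.5): a purely
out-of-band residue is periodic and would otherwise satisfy any
self-relative threshold.

**Beat amplitudes.** Peak and trough indices are located on the smoothed
(50 ms moving average) IR pulse signal — the peak within ±0.2·IBI of the
beat, the trough in the preceding 0.55·IBI — and *both* channels are read
at the same indices. Common anchoring avoids the upward bias that
channel-wise extremum picking would give the weaker (red) channel, which
would otherwise bias Ω and hence SpO₂.

**Pulse rate.** Per second, the trailing 8-s IR AC segment is
Hann-windowed, zero-padded to ≤ 0.05 Hz bin spacing, and the magnitude
spectrum maximum inside 0.5–3.67 Hz is refined by 3-point parabolic
interpolation (worst-case quantisation ≈ 0.6 bpm). A peak below twice the
median band power, or a window with no pulsatile content, reports missing.
Band restriction is the artifact defence: 23.5 Hz = 1410 bpm and 31.3 Hz
= 1878 bpm cannot be selected.

**SpO₂.** Per second, Ω is the median beat-wise ratio-of-ratios over the
trailing 5-s window (≥ 2 beats required), mapped through the calibration
and clipped to [50, 100] %.

**SQI windows.** 5-s windows slide at 0.2 Hz (trailing, half-open — the
alignment is a design choice; see below). Moment SQIs use population (1/N)
moments on the detrended AC window; entropy first centres and normalises
the window to unit energy so xᵢ² is a probability density and the index is
scale-invariant with maximum ln N. PI uses the median per-beat
peak-to-trough (robust to single outlier beats) with a 2√2·RMS fallback
when fewer than two beats are in the window.

**QI proxy.** 100 × (power within ±0.15 Hz of the PR fundamental and its
first harmonic) / (total power 0.5–40 Hz) on the linearly detrended raw
window, using the *unpadded* rectangular periodogram, whose bins partition
the window power exactly (Parseval); zero-padding would leak sinc-sidelobe
energy out of the numerator band and cap the score well below 100 even for
a perfectly periodic pulse. The 0.5–40 Hz denominator includes the rotor
harmonics, so QI is the one index with a built-in (small) artifact
sensitivity.

**VPD proxy.** A beat is valid iff its IBI is in [300, 2000] ms, within
±30 % of the running median of the last 8 IBIs, and its waveform
(resampled to 60 points, z-scored) correlates ≥ 0.8 with the running
template (mean of the last 8 valid beats). QI and VPD are documented
proxies: the in-ear device's algorithms are proprietary, so only their
published semantics (0–100 dominance; % valid beats) are reproduced, never
their exact values.

**Resampling rules.** Both resamplers use trailing half-open windows
(t − w, t]: a 5-s moving average to 0.2 Hz for SQIs, and 30-s sampling
with an 8-s pre-window mean for vitals. Trailing alignment is causal,
matching an online monitor; windows without input yield explicit missing
values, and study-level statistics skip missings with a logged count.

**Spectra.** Welch periodograms (Hann, segments ≤ 2¹⁴ samples, 50 %
overlap) rather than a single FFT, for stable peaks on 10-min records.
Accelerometer spectra use the Euclidean magnitude minus its mean. Peak
frequencies are refined parabolically; emergent in-flight peaks are
frequencies where in-flight power exceeds no-flight power by ≥ 10 dB above
10 Hz, clustered with a 0.5 Hz gap tolerance so amplitude-modulation
sidebands stay with their carrier.

## Statistics

Per SQI, per-subject phase means are compared in-flight vs no-flight:
Shapiro–Wilk on the paired differences routes to the paired t-test
(df = n − 1) when normality is not rejected at α = 0.05, else to the
Wilcoxon signed-rank test. The Wilcoxon statistic is V (sum of positive
ranks); p is exact by enumeration (dynamic programming over rank sums) for
≤ 25 nonzero differences without ties, else a normal approximation with
tie and continuity corrections; the z value is reported alongside V.
All-zero differences are reported as "no difference" (p = 1). No
multiple-testing correction is applied across the eleven SQI tests; the
report carries the count so readers can judge the family-wise level —
with ~11 correlated tests, some seed realisations will produce a p < 0.05
under a true null.

Agreement per vital sign and phase pools all subjects' 30-s samples:
Bland–Altman bias and limits of agreement (bias ± 1.96 × sample SD of the
differences), Lin's CCC with population moments (the (n − 1) alternative
changes values at these n by well under 1 %), and McBride categories
(> 0.99 almost perfect; > 0.95 substantial; > 0.90 moderate; otherwise
poor).

## Problem sizes

The default study is 16 subjects × 2 phases × 600 s (PPG at 200 Hz, accel
at 400 Hz), the size the analysis is designed around. Unit and property
tests use 60–120 s records and 2–4 subjects, which is ample for every
windowed quantity; tests that estimate spectral noise floors use full
600-s records because the Welch floor needs ≥ ~10 averaged segments to be
stable.

## What the generator does and does not emulate

Emulated: pulsatile two-wavelength PPG with realistic perfusion, drift,
respiration and noise; SpO₂-controlled channel ratio; AR(1) heart-rhythm
variability; amplitude-modulated narrow-band vibration artifacts in PPG
and accelerometer; reference-monitor averaging rules and an ear-vs-finger
SpO₂ site offset; between-phase within-subject physiological state
changes.

Not emulated: gross motion artifacts and sensor displacement (beats are
never destroyed, so VPD is higher and less variable than on ambulatory
device data); biomechanical seat-to-head transfer beyond a scalar damping;
posture, motion-sickness and thermoregulation physiology; the proprietary
device calibration and firmware quality scores. Passing tests therefore
demonstrate the *pipeline's* correctness and the stated robustness
properties under these study conditions, not device-level performance on
real recordings.

## Numerical conventions and degenerate inputs

- Time is seconds from recording start, double precision; phases are
  separate records.
- Population (1/N) moments throughout the SQI formulas; sample (n − 1) SD
  in the paired t-test and Bland–Altman.
- Zero-variance windows yield missing moments; all-zero windows yield
  missing entropy; 0·ln 0 ≡ 0.
- Constant records yield no beats; a window with no pulsatile content
  (std below 10⁻⁹ of the raw intensity scale) reports missing PR.
- Parabolic peak refinement is clamped to ±0.5 bin; boundary bins are not
  refined.
- CSVs are written at repr precision and round-trip exactly at double
  precision.
- Seeds: every random quantity derives from `(master_seed, stream key)`
  through `numpy.random.default_rng`, so any artifact is reproducible from
  the master seed alone.

## Known limitations

- The linear SpO₂ calibration is conventional, not device-specific; Ω
  levels are therefore internally consistent but not comparable to
  published device Ω values.
- The QI/VPD proxies preserve semantics, not firmware values.
- The minimum p-value over the eleven null phase comparisons is a
  stochastic quantity: even with no artifact effect, a fraction of seeds
  produces a single p < 0.05, exactly as a real replication of the
  protocol would.
- Entropy of well-formed 5-s windows is always close to its ln N ceiling;
  its discriminative range is narrow by construction of the formula.
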
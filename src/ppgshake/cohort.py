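"""Synthetic cohort generator for the vibration-exposure study.

Generates, per virtual subject and per protocol phase (10 min seated rest
``no_flight``, 10 min simulated cabin vibration ``in_flight``):

* a two-wavelength in-ear PPG record (200 Hz) — pulsatile AC on a slowly
  drifting DC baseline, downward pulses (absorbance rises with blood volume),
  an SpO₂-controlled red/infrared amplitude ratio, sensor noise, and during
  the in-flight phase two amplitude-modulated rotor-harmonic artifact tones
  (defaults 23.5 Hz and 31.3 Hz) added to both optical channels;
* a tri-axial accelerometer record (400 Hz) with the same rotor harmonics
  around the 1 g gravity baseline;
* emulated clinical-reference vitals at 1 Hz (trimmed 10-R-R heart rate and
  8-s-averaged finger SpO₂ with an ear-vs-finger site offset).

Every artifact is a pure function of ``(CohortConfig, master_seed)``.

A latent per-(subject, phase) physiological state ``g ~ N(0, 1)`` jointly
shifts heart rate, pulsatile amplitude, noise level and SpO₂ between phases.
This emulates the within-subject between-phase variation seen in resting
recordings and makes the phase differences of all quality indices share one
dominant source of variance, as they do in real repeated measurements.
"""
from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ParameterError
from .filters import bandpass
from .io import write_timeseries_csv
from .types import AccelRecord, BeatSeries, PPGRecord, ReferenceVitals, VitalsSeries
from .vitals import reference_hr, reference_spo2


@dataclass
class SubjectParams:
    """Ground-truth physiological and sensor parameters of one virtual subject."""

    subject_id: str
    hr_mean: float  # bpm
    hr_sd_within: float  # bpm, stationary SD of the AR(1) inter-beat process
    spo2_true: float  # %
    pi_target: float  # % perfusion index (AC peak-to-trough / DC)
    dc_ir: float  # a.u.
    dc_r: float  # a.u.
    resp_rate: float  # Hz
    noise_sd: float  # a.u., white sensor noise per channel
    pert_sd: float  # a.u., common-mode 10–40 Hz perturbation component
    seed: int

    def __post_init__(self) -> None:
        if not (40.0 <= self.hr_mean <= 120.0):
            raise ParameterError(f"hr_mean {self.hr_mean} outside [40, 120] bpm")
        if not (85.0 <= self.spo2_true <= 100.0):
            raise ParameterError(f"spo2_true {self.spo2_true} outside [85, 100] %")
        if self.pi_target <= 0:
            raise ParameterError("pi_target must be positive")


@dataclass
class VibrationProfile:
    """Rotor-harmonic vibration injected during the in-flight phase."""

    freqs: tuple[float, ...] = (23.5, 31.3)  # Hz
    rel_amplitude: float = 0.10  # fraction of the PPG AC amplitude
    accel_amplitudes: tuple[float, ...] = (0.05, 0.03)  # g per frequency
    am_depth: float = 0.2  # amplitude-modulation depth (flight-maneuver modulation)
    am_rate: float = 0.1  # Hz

    def __post_init__(self) -> None:
        if any(f <= 10.0 for f in self.freqs):
            raise ParameterError("vibration frequencies must lie above the pulse band (>10 Hz)")
        if self.rel_amplitude < 0:
            raise ParameterError("rel_amplitude must be ≥ 0")
        if len(self.accel_amplitudes) != len(self.freqs):
            raise ParameterError("need one accelerometer amplitude per frequency")


@dataclass
class CohortConfig:
    """Study-level configuration (16 subjects × 2 × 10 min by default)."""

    n_subjects: int = 16
    phase_duration_s: float = 600.0
    fs_ppg: float = 200.0
    fs_accel: float = 400.0
    calibration: tuple[float, float] = (110.0, 25.0)  # SpO₂ = a − b·Ω
    master_seed: int = 0
    spo2_site_offset: float = -1.0  # reference (finger) minus ear-site SpO₂, %

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be ≥ 2")
        if self.phase_duration_s < 60:
            raise ParameterError("phase_duration_s must be ≥ 60 s")


@dataclass
class SubjectData:
    """All generated artifacts for one subject."""

    params: SubjectParams
    phase_g: dict[str, float]
    phase_params: dict[str, SubjectParams]
    beats: dict[str, BeatSeries]
    ppg: dict[str, PPGRecord]
    accel: dict[str, AccelRecord]
    ref: dict[str, ReferenceVitals]


def _trunc_normal(rng: np.random.Generator, mu: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        v = rng.normal(mu, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mu, lo, hi))


def sample_subject(cohort: CohortConfig, index: int) -> SubjectParams:
    """Draw one subject's parameters, deterministic given (master_seed, index).

    Heart rate is Normal(70, 11) bpm truncated to [45, 110]; SpO₂ is
    Normal(96.5, 1.2)% truncated to [90, 100]; perfusion index is log-normal
    with median 1.0%.
    """
    if not (0 <= index < cohort.n_subjects):
        raise ParameterError(f"subject index {index} out of range 0..{cohort.n_subjects - 1}")
    rng = np.random.default_rng([cohort.master_seed, 7, index])
    hr_mean = _trunc_normal(rng, 70.0, 11.0, 45.0, 110.0)
    spo2_true = _trunc_normal(rng, 96.5, 1.2, 90.0, 100.0)
    pi_target = float(np.clip(np.exp(rng.normal(np.log(1.0), 0.45)), 0.3, 3.0))
    dc_ir = 2.0 * float(np.exp(rng.normal(0.0, 0.15)))
    dc_r = dc_ir * 0.95 * float(np.exp(rng.normal(0.0, 0.10)))
    hr_sd_within = 2.0 * float(np.exp(rng.normal(0.0, 0.3)))
    resp_rate = float(np.clip(rng.normal(0.25, 0.04), 0.15, 0.40))
    noise_sd = 0.0012 * dc_ir * float(np.exp(rng.normal(0.0, 0.4)))
    pert_sd = 0.0026 * dc_ir * float(np.exp(rng.normal(0.0, 0.35)))
    seed = int(rng.integers(2**31))
    return SubjectParams(
        subject_id=f"S{index:02d}",
        hr_mean=hr_mean,
        hr_sd_within=hr_sd_within,
        spo2_true=spo2_true,
        pi_target=pi_target,
        dc_ir=dc_ir,
        dc_r=dc_r,
        resp_rate=resp_rate,
        noise_sd=noise_sd,
        pert_sd=pert_sd,
        seed=seed,
    )


# latent-state couplings (per unit g): bpm shift, log amplitude, log noise, % SpO₂
_G_HR = 2.5
_G_AMP = 0.12
_G_NOISE = -0.25
_G_SPO2 = 0.25


def apply_phase_state(params: SubjectParams, g: float) -> SubjectParams:
    """Return phase-adjusted parameters for latent physiological state ``g``."""
    return replace(
        params,
        hr_mean=float(np.clip(params.hr_mean + _G_HR * g, 40.0, 120.0)),
        pi_target=params.pi_target * float(np.exp(_G_AMP * g)),
        noise_sd=params.noise_sd * float(np.exp(_G_NOISE * g)),
        pert_sd=params.pert_sd * float(np.exp(_G_NOISE * g)),
        spo2_true=float(np.clip(params.spo2_true + _G_SPO2 * g, 85.0, 100.0)),
    )


def synth_beats(
    params: SubjectParams, duration_s: float, rng: np.random.Generator | None = None
) -> BeatSeries:
    """Ground-truth cardiac rhythm: AR(1) inter-beat intervals covering [0, duration].

    The IBI process has mean 60000/hr_mean ms and stationary SD mapped from
    ``hr_sd_within`` (bpm); every interval is clipped to [300, 2000] ms.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    if rng is None:
        rng = np.random.default_rng([params.seed, 0])
    mean_ms = 60000.0 / params.hr_mean
    sd_ms = 60000.0 * params.hr_sd_within / params.hr_mean**2
    phi = 0.85
    innov_sd = sd_ms * np.sqrt(1.0 - phi**2)
    times = [float(rng.uniform(0.0, mean_ms / 1000.0))]
    dev = rng.normal(0.0, sd_ms) if sd_ms > 0 else 0.0
    while times[-1] <= duration_s:
        ibi = float(np.clip(mean_ms + dev, 300.0, 2000.0))
        times.append(times[-1] + ibi / 1000.0)
        dev = phi * dev + (rng.normal(0.0, innov_sd) if innov_sd > 0 else 0.0)
    return BeatSeries(peak_times=np.asarray(times))


def _unit_pulse_train(t: np.ndarray, beats: BeatSeries, fs: float) -> np.ndarray:
    """Sum-of-two-Gaussians pulse template per beat, unit peak-to-trough (median).

    Systolic Gaussian centred on the beat time (width 0.13·IBI), dicrotic wave
    at 45% of the IBI after it (width 0.15·IBI, amplitude 0.20).  Widths scale
    with the local IBI so slow and fast hearts produce self-similar pulses.
    """
    train = np.zeros_like(t)
    times = beats.peak_times
    ibis_s = np.diff(times)
    n = len(t)
    for k, tau in enumerate(times):
        if k > 0:
            ibi = ibis_s[k - 1]
        elif len(ibis_s):
            ibi = ibis_s[0]
        else:
            ibi = 1.0
        lo = max(int((tau - 0.6 * ibi) * fs), 0)
        hi = min(int((tau + 1.1 * ibi) * fs) + 1, n)
        if hi <= lo:
            continue
        tt = t[lo:hi]
        train[lo:hi] += np.exp(-0.5 * ((tt - tau) / (0.13 * ibi)) ** 2)
        train[lo:hi] += 0.20 * np.exp(-0.5 * ((tt - tau - 0.45 * ibi) / (0.15 * ibi)) ** 2)
    # normalise so the median per-beat peak-to-trough is exactly 1
    p2t = []
    for k in range(1, len(times) - 1):
        lo = int((times[k] - 0.5 * ibis_s[k - 1]) * fs)
        hi = int((times[k] + 0.5 * ibis_s[k]) * fs)
        if 0 <= lo < hi <= n:
            seg = train[lo:hi]
            p2t.append(seg.max() - seg.min())
    scale = np.median(p2t) if p2t else (train.max() - train.min() or 1.0)
    return train / scale


def synth_ppg(
    params: SubjectParams,
    beats: BeatSeries,
    profile: VibrationProfile | None,
    cohort: CohortConfig,
    rng: np.random.Generator | None = None,
    phase: str = "no_flight",
) -> PPGRecord:
    """Generate the two-channel PPG record for one phase.

    ``ir = dc_ir·(1 + drift + resp) − pulse_ir + noise`` with downward pulses;
    the red channel shares the pulse shape with its AC/DC ratio scaled so that
    Ω = (AC_R/DC_R)/(AC_IR/DC_IR) equals (a − spo2_true)/b under the cohort
    calibration.  When ``profile`` is given, amplitude-modulated artifact tones
    are added to both channels.
    """
    if rng is None:
        rng = np.random.default_rng([params.seed, 1])
    a, b = cohort.calibration
    omega_true = (a - params.spo2_true) / b
    if not (0.0 < omega_true <= 2.0):
        raise ParameterError(
            f"spo2_true={params.spo2_true} incompatible with calibration (Ω={omega_true:.3f})"
        )
    fs = cohort.fs_ppg
    n = int(round(cohort.phase_duration_s * fs))
    t = np.arange(n) / fs

    train = _unit_pulse_train(t, beats, fs)
    amp_ir = params.pi_target / 100.0 * params.dc_ir
    amp_r = omega_true * (amp_ir / params.dc_ir) * params.dc_r

    phi_drift, phi_resp = rng.uniform(0, 2 * np.pi, size=2)
    baseline = 1.0 + 0.01 * np.sin(2 * np.pi * 0.01 * t + phi_drift)
    baseline += 0.005 * np.sin(2 * np.pi * params.resp_rate * t + phi_resp)

    ir = params.dc_ir * baseline - amp_ir * train
    red = params.dc_r * baseline - amp_r * train

    # common-mode perturbation above the pulse band (tissue/contact), scaled by DC
    pert = rng.standard_normal(n)
    pert = bandpass(pert, fs, (10.0, 40.0))
    sd = pert.std()
    if sd > 0:
        pert /= sd
    frac = params.pert_sd / params.dc_ir
    ir += frac * params.dc_ir * pert
    red += frac * params.dc_r * pert
    # independent white sensor noise per channel
    if params.noise_sd > 0:
        ir += params.noise_sd * rng.standard_normal(n)
        red += params.noise_sd * (params.dc_r / params.dc_ir) * rng.standard_normal(n)

    if profile is not None and profile.rel_amplitude > 0:
        mod = 1.0 + profile.am_depth * np.sin(
            2 * np.pi * profile.am_rate * t + rng.uniform(0, 2 * np.pi)
        )
        artifact = np.zeros(n)
        for f in profile.freqs:
            artifact += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        artifact *= profile.rel_amplitude * amp_ir * mod
        ir += artifact
        red += artifact

    return PPGRecord(red=red, ir=ir, fs=fs, phase=phase, subject_id=params.subject_id)


def synth_accel(
    profile: VibrationProfile,
    duration_s: float,
    fs: float = 400.0,
    location: str = "seat",
    rng: np.random.Generator | None = None,
    subject_id: str = "S00",
    noise_sd: float = 0.01,
) -> AccelRecord:
    """Accelerometer record: gravity plus rotor-harmonic tones plus white noise.

    The head location damps vibration amplitudes by a factor 0.7 (seat-to-head
    transmission through cushion and body); ax and ay are attenuated copies
    (×0.3) with independent phases.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    damp = 0.7 if location == "head" else 1.0
    az = np.ones(n)
    ax = np.zeros(n)
    ay = np.zeros(n)
    for f, amp in zip(profile.freqs, profile.accel_amplitudes):
        az += damp * amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        ax += damp * 0.3 * amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        ay += damp * 0.3 * amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    az += noise_sd * rng.standard_normal(n)
    ax += noise_sd * rng.standard_normal(n)
    ay += noise_sd * rng.standard_normal(n)
    return AccelRecord(ax=ax, ay=ay, az=az, fs=fs, location=location, subject_id=subject_id)


def synth_reference_vitals(
    params: SubjectParams,
    beats: BeatSeries,
    duration_s: float,
    rng: np.random.Generator | None = None,
    site_offset: float = -1.0,
    hr_jitter_sd: float = 0.5,
    spo2_noise_sd: float = 0.4,
) -> ReferenceVitals:
    """Emulate the clinical monitor at 1 Hz from the ground-truth rhythm.

    HR follows the monitor rule (mean of the latest 10 R-R intervals after
    excluding the two longest and two shortest) plus small display jitter;
    SpO₂ is the true value plus the ear-vs-finger site offset (default −1.0%
    on the ear-minus-finger convention, i.e. the finger reads 1% lower) and
    measurement noise, smoothed by the monitor's trailing 8-s mean.
    """
    if rng is None:
        rng = np.random.default_rng([params.seed, 2])
    t = np.arange(1.0, np.floor(duration_s) + 1.0)
    times = beats.peak_times
    hr = np.full(len(t), np.nan)
    for i, tk in enumerate(t):
        idx = np.searchsorted(times, tk, side="right")
        ibis = np.diff(times[:idx]) * 1000.0
        if len(ibis) >= 10:
            hr[i] = reference_hr(ibis[-10:])
    if hr_jitter_sd > 0:
        hr = hr + hr_jitter_sd * rng.standard_normal(len(t))
    raw_spo2 = np.full(len(t), params.spo2_true + site_offset)
    if spo2_noise_sd > 0:
        raw_spo2 += spo2_noise_sd * rng.standard_normal(len(t))
    spo2 = reference_spo2(raw_spo2)
    return ReferenceVitals(t=t, hr_ref=hr, spo2_ref=spo2)


def generate_cohort(
    cohort: CohortConfig,
    profile: VibrationProfile | None = None,
    out_dir: str | os.PathLike | None = None,
) -> list[SubjectData]:
    """Generate the full cohort: per subject, both phases of PPG, accelerometer
    and reference vitals.  No-flight records carry no vibration; in-flight
    records carry the profile.  Fully reproducible from ``master_seed``.

    When ``out_dir`` is given, writes per-subject CSVs (PPG, accel, reference
    vitals) and a ``ground_truth.json`` with the generating parameters.
    """
    if profile is None:
        profile = VibrationProfile()
    quiet = replace(
        profile, rel_amplitude=0.0, accel_amplitudes=tuple(0.0 for _ in profile.freqs)
    )
    subjects: list[SubjectData] = []
    for index in range(cohort.n_subjects):
        params = sample_subject(cohort, index)
        data = SubjectData(
            params=params, phase_g={}, phase_params={}, beats={}, ppg={}, accel={}, ref={}
        )
        for p_idx, phase in enumerate(("no_flight", "in_flight")):
            base = [cohort.master_seed, 11, index, p_idx]
            g = float(np.random.default_rng(base + [0]).standard_normal())
            padj = apply_phase_state(params, g)
            beats = synth_beats(
                padj, cohort.phase_duration_s, rng=np.random.default_rng(base + [1])
            )
            phase_profile = profile if phase == "in_flight" else None
            ppg = synth_ppg(
                padj,
                beats,
                phase_profile,
                cohort,
                rng=np.random.default_rng(base + [2]),
                phase=phase,
            )
            accel = synth_accel(
                profile if phase == "in_flight" else quiet,
                cohort.phase_duration_s,
                fs=cohort.fs_accel,
                location="seat",
                rng=np.random.default_rng(base + [3]),
                subject_id=params.subject_id,
            )
            ref = synth_reference_vitals(
                padj,
                beats,
                cohort.phase_duration_s,
                rng=np.random.default_rng(base + [4]),
                site_offset=cohort.spo2_site_offset,
            )
            data.phase_g[phase] = g
            data.phase_params[phase] = padj
            data.beats[phase] = beats
            data.ppg[phase] = ppg
            data.accel[phase] = accel
            data.ref[phase] = ref
        subjects.append(data)

    if out_dir is not None:
        for data in subjects:
            sdir = os.path.join(out_dir, data.params.subject_id)
            os.makedirs(sdir, exist_ok=True)
            truth = {"params": dataclasses.asdict(data.params), "phase_g": data.phase_g}
            for phase in ("no_flight", "in_flight"):
                write_timeseries_csv(data.ppg[phase], os.path.join(sdir, f"{phase}_ppg.csv"))
                write_timeseries_csv(data.accel[phase], os.path.join(sdir, f"{phase}_accel.csv"))
                ref = data.ref[phase]
                vs = VitalsSeries(
                    t=ref.t,
                    pr_ear=np.full(len(ref), np.nan),
                    spo2_ear=np.full(len(ref), np.nan),
                    hr_ref=ref.hr_ref,
                    spo2_ref=ref.spo2_ref,
                )
                write_timeseries_csv(vs, os.path.join(sdir, f"{phase}_ref.csv"))
            with open(os.path.join(sdir, "ground_truth.json"), "w") as fh:
                json.dump(truth, fh, indent=2)
    return subjects
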
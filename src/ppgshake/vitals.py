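"""Pulse-rate and SpO₂ extraction from PPG, plus the clinical-reference rules.

Pulse rate is the dominant spectral frequency of the trailing 8-s infrared AC
segment inside the physiological band (default 0.5–3.67 Hz, i.e. 30–220 bpm),
refined by parabolic peak interpolation.  Restricting the search to that band
is what makes the estimate immune to rotor-harmonic artifacts at 23.5 Hz
(1410 bpm) and 31.3 Hz (1878 bpm): they simply cannot be selected.

SpO₂ uses the beat-wise ratio of ratios Ω = (AC_R/DC_R)/(AC_IR/DC_IR) mapped
through a linear calibration curve SpO₂ = a − b·Ω.

The reference monitor is emulated by its published rules: heart rate is the
mean of the latest 10 R-R intervals after excluding the two longest and the
two shortest; reference SpO₂ is a trailing 8-second mean.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import DataError, ParameterError
from .filters import beat_amplitudes, decompose_channel
from .io import vitals_sample
from .types import BeatSeries, PPGRecord, ReferenceVitals, VitalsSeries


@dataclass
class PRConfig:
    """Pulse-rate estimator settings."""

    band: tuple[float, float] = (0.5, 3.67)  # Hz; 30–220 bpm
    window_s: float = 8.0
    update_s: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.band[0] < self.band[1]):
            raise ParameterError("PR band must satisfy 0 < low < high")


@dataclass
class CalibrationCurve:
    """Linear SpO₂ calibration SpO₂ = a − b·Ω, clipped to a plausible range."""

    a: float = 110.0
    b: float = 25.0
    clip: tuple[float, float] = (50.0, 100.0)

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ParameterError("calibration slope b must be positive")

    def spo2(self, omega: float | np.ndarray) -> float | np.ndarray:
        return np.clip(self.a - self.b * np.asarray(omega, dtype=float), *self.clip)


def detect_beats(ac: np.ndarray, fs: float) -> BeatSeries:
    """Peak picking on a pulse-oriented (pulse-up), band-passed AC signal.

    Local maxima with minimum separation 0.3 s and prominence at least
    0.4 × the 90th percentile of |ac| over the trailing 10 s (an adaptive
    threshold, so detection survives amplitude changes mid-record).

    A band-dominance gate rejects signals whose energy does not lie in the
    pulse band: out-of-band residues (e.g. a rotor-harmonic tone attenuated
    by the band-pass) are periodic and would otherwise satisfy any
    self-relative threshold.  The gate computes, per 2-s block, the fraction
    of variance below 8 Hz; if the median fraction is under 0.5 the record
    contains no pulsatile signal and no beats are returned.
    """
    ac = np.asarray(ac, dtype=float)
    if len(ac) == 0 or np.allclose(ac, ac[0] if len(ac) else 0.0):
        return BeatSeries(peak_times=np.array([]))
    if len(ac) >= 4 * fs:
        from .filters import lowpass

        low = lowpass(ac, fs, 8.0)
        block = int(2 * fs)
        n_blocks = len(ac) // block
        fracs = []
        for i in range(n_blocks):
            seg = ac[i * block : (i + 1) * block]
            v = np.var(seg)
            if v > 0:
                fracs.append(np.var(low[i * block : (i + 1) * block]) / v)
        if fracs and np.median(fracs) < 0.5:
            return BeatSeries(peak_times=np.array([]))
    peaks, props = sps.find_peaks(ac, distance=max(int(0.3 * fs), 1), prominence=1e-12)
    if len(peaks) == 0:
        return BeatSeries(peak_times=np.array([]))
    # trailing 10-s 90th percentile of |ac|, evaluated on 0.5-s blocks
    block = max(int(0.5 * fs), 1)
    n_blocks = int(np.ceil(len(ac) / block))
    absac = np.abs(ac)
    bq = np.array(
        [np.quantile(absac[i * block : (i + 1) * block], 0.9) for i in range(n_blocks)]
    )
    trail = np.empty(n_blocks)
    for i in range(n_blocks):
        lo = max(i - 19, 0)
        trail[i] = np.quantile(bq[lo : i + 1], 0.9) if i > lo else bq[i]
    thresh = 0.4 * trail[np.minimum(peaks // block, n_blocks - 1)]
    keep = props["prominences"] >= thresh
    return BeatSeries(peak_times=peaks[keep] / fs)


def _parabolic_refine(power: np.ndarray, idx: int) -> float:
    """Fractional-bin offset of a peak by 3-point parabolic interpolation."""
    if idx <= 0 or idx >= len(power) - 1:
        return 0.0
    y0, y1, y2 = power[idx - 1], power[idx], power[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))


def pulse_rate(
    record: PPGRecord, cfg: PRConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pulse rate (bpm) at 1 Hz from the dominant IR AC spectral peak.

    Each second, the trailing ``window_s`` segment of the infrared AC signal
    is Hann-windowed, zero-padded to ≤ 0.05 Hz bin spacing and searched for
    the maximum of the magnitude spectrum inside ``cfg.band``; the peak is
    refined by 3-point parabolic interpolation.  Seconds whose peak does not
    rise above twice the median band power are reported missing, as are
    warm-up seconds before one full window is available.
    """
    cfg = cfg or PRConfig()
    fs = record.fs
    if record.duration < cfg.window_s:
        raise DataError("record shorter than the PR analysis window")
    ac, _ = decompose_channel(record.ir, fs)
    pulse = -ac  # downward intensity pulses -> pulse-up orientation
    win = int(round(cfg.window_s * fs))
    nfft = 1 << int(np.ceil(np.log2(fs / 0.05)))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    band = (freqs >= cfg.band[0]) & (freqs <= cfg.band[1])
    band_idx = np.flatnonzero(band)
    hann = np.hanning(win)

    t_grid = np.arange(1.0, np.floor(record.duration) + 1.0)
    pr = np.full(len(t_grid), np.nan)
    starts = []
    rows = []
    # scale floor: a window whose AC content is numerically zero relative to
    # the raw intensity has no pulsatile signal and must report missing
    scale = float(np.mean(np.abs(record.ir))) + 1e-30
    for i, tk in enumerate(t_grid):
        end = int(round(tk * fs))
        if end < win:
            continue
        if np.std(pulse[end - win : end]) < 1e-9 * scale:
            continue
        starts.append(i)
        rows.append(pulse[end - win : end] * hann)
    if rows:
        spec = np.abs(np.fft.rfft(np.asarray(rows), n=nfft, axis=1)) ** 2
        for j, i in enumerate(starts):
            p = spec[j, band_idx]
            k = int(np.argmax(p))
            if p[k] < 2.0 * np.median(p) or p[k] <= 0:
                continue
            delta = _parabolic_refine(p, k)
            f = freqs[band_idx[0]] + (k + delta) * (freqs[1] - freqs[0])
            pr[i] = 60.0 * f
    return t_grid, pr


def spo2(
    record: PPGRecord,
    curve: CalibrationCurve | None = None,
    window_s: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """SpO₂ (%) at 1 Hz from beat-wise ratio-of-ratios on a trailing window.

    Per second, Ω is the median beat-wise (AC_R/DC_R)/(AC_IR/DC_IR) over the
    trailing ``window_s`` window; seconds with fewer than two usable beats are
    missing.
    """
    curve = curve or CalibrationCurve()
    fs = record.fs
    ac_ir, dc_ir = decompose_channel(record.ir, fs)
    ac_r, dc_r = decompose_channel(record.red, fs)
    pulse_ir = -ac_ir
    beats = detect_beats(pulse_ir, fs)
    t_grid = np.arange(1.0, np.floor(record.duration) + 1.0)
    out = np.full(len(t_grid), np.nan)
    if len(beats) < 2:
        return t_grid, out
    amps = beat_amplitudes(
        pulse_ir,
        beats,
        fs,
        channels={"ir": pulse_ir, "r": -ac_r},
        dc={"ir": dc_ir, "r": dc_r},
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = (amps["r"] / amps["dc_r"]) / (amps["ir"] / amps["dc_ir"])
    good = np.isfinite(ratios) & (amps["ir"] > 0) & (amps["r"] > 0)
    bt, ratios = amps["t"][good], ratios[good]
    for i, tk in enumerate(t_grid):
        sel = (bt > tk - window_s) & (bt <= tk)
        if np.count_nonzero(sel) >= 2:
            out[i] = curve.spo2(float(np.median(ratios[sel])))
    return t_grid, out


def reference_hr(ibis) -> float:
    """Monitor HR rule: trimmed mean of the latest 10 R-R intervals (ms).

    The two longest and the two shortest of the ten are excluded; HR is
    60000 / mean of the remaining six.  Fewer than ten intervals → NaN.
    """
    ibis = np.asarray(ibis, dtype=float)
    if len(ibis) < 10:
        return float("nan")
    last = np.sort(ibis[-10:])
    return 60000.0 / float(np.mean(last[2:8]))


def reference_spo2(raw: np.ndarray) -> np.ndarray:
    """Monitor SpO₂ rule: trailing 8-sample mean of a 1 Hz series.

    The first seven samples are missing (warm-up).
    """
    raw = np.asarray(raw, dtype=float)
    out = np.full(len(raw), np.nan)
    if len(raw) >= 8:
        c = np.concatenate([[0.0], np.cumsum(raw)])
        out[7:] = (c[8:] - c[:-8]) / 8.0
    return out


def build_vitals_series(
    t_pr: np.ndarray,
    pr_ear: np.ndarray,
    t_spo2: np.ndarray,
    spo2_ear: np.ndarray,
    ref: ReferenceVitals,
    step_s: float = 30.0,
    pre_window_s: float = 8.0,
) -> VitalsSeries:
    """Assemble the 30-s comparison grid: ear vitals via the trailing 8-s mean,
    reference vitals sampled at the same instants, bias implied (ear − ref)."""
    g1, pr30 = vitals_sample(t_pr, pr_ear, step_s=step_s, pre_window_s=pre_window_s)
    g2, sp30 = vitals_sample(t_spo2, spo2_ear, step_s=step_s, pre_window_s=pre_window_s)
    if len(g1) != len(g2) or (len(g1) and np.max(np.abs(g1 - g2)) > 1e-9):
        raise DataError("ear PR and SpO₂ streams are not on a common time origin")
    hr_ref = np.full(len(g1), np.nan)
    spo2_ref = np.full(len(g1), np.nan)
    for i, tk in enumerate(g1):
        j = np.searchsorted(ref.t, tk + 1e-9) - 1
        if 0 <= j < len(ref.t) and abs(ref.t[j] - tk) <= step_s:
            hr_ref[i] = ref.hr_ref[j]
            spo2_ref[i] = ref.spo2_ref[j]
    # clip tiny numerical overshoots of physiologic bounds introduced by averaging
    sp30 = np.clip(sp30, 50.0, 100.0)
    spo2_ref = np.clip(spo2_ref, 50.0, 100.0)
    return VitalsSeries(t=g1, pr_ear=pr30, spo2_ear=sp30, hr_ref=hr_ref, spo2_ref=spo2_ref)
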
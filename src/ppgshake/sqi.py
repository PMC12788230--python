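"""Signal-quality indices on sliding 5-s windows, assembled at 0.2 Hz.

Seven index families are computed per window: perfusion index, skewness,
entropy, excess kurtosis, the red/infrared ratio-of-ratios Ω, a 0–100
spectral-dominance quality indicator (QI) and the percentage of valid pulses
(VPD).  Moment-based indices use population (1/N) moments and operate on the
detrended pulsatile (AC) window; computing them on the raw DC-dominated
samples would make them baseline artifacts.

QI and VPD are documented proxies for the in-ear device's proprietary
algorithms: they preserve the published semantics (0–100 dominance score;
percentage of beats passing physiological and template-similarity checks)
with fixed, stated thresholds, without claiming to reproduce the firmware's
exact numbers.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import DataError, ParameterError
from .filters import decompose_channel
from .types import (
    BeatSeries,
    ChannelComponents,
    PPGRecord,
    SignalWindow,
    SQI_COLUMNS,
    SQISeries,
)
from .vitals import detect_beats, pulse_rate
from .filters import beat_amplitudes


@dataclass
class SQIWindowConfig:
    window_s: float = 5.0
    pulse_band: tuple[float, float] = (0.5, 10.0)
    dc_cutoff: float = 0.4
    out_rate_hz: float = 0.2

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ParameterError("window_s must be positive")
        if not (self.pulse_band[0] < self.pulse_band[1]):
            raise ParameterError("pulse band low must be below high")


def decompose_ac_dc(record: PPGRecord, cfg: SQIWindowConfig | None = None):
    """AC/DC split of both optical channels.

    Returns ``(ac_ir, dc_ir, ac_red, dc_red)``; zero-phase filters, so
    ``raw ≈ dc + ac`` up to the out-of-band residue, with edge effects
    confined to about one filter settling length.
    """
    cfg = cfg or SQIWindowConfig()
    ac_ir, dc_ir = decompose_channel(record.ir, record.fs, cfg.dc_cutoff, cfg.pulse_band)
    ac_r, dc_r = decompose_channel(record.red, record.fs, cfg.dc_cutoff, cfg.pulse_band)
    return ac_ir, dc_ir, ac_r, dc_r


def _samples(window) -> np.ndarray:
    if isinstance(window, SignalWindow):
        return window.samples
    return np.asarray(window, dtype=float)


def skewness(window) -> float:
    """Population skewness (1/N)·Σ((x − μ̂)/σ)³; zero variance → NaN."""
    x = _samples(window)
    if len(x) < 3:
        raise DataError("skewness needs at least 3 samples")
    mu = x.mean()
    sigma = x.std()
    if sigma == 0:
        return float("nan")
    return float(np.mean(((x - mu) / sigma) ** 3))


def kurtosis(window) -> float:
    """Population excess kurtosis (1/N)·Σ((x − μ̂)/σ)⁴ − 3; zero variance → NaN."""
    x = _samples(window)
    if len(x) < 4:
        raise DataError("kurtosis needs at least 4 samples")
    mu = x.mean()
    sigma = x.std()
    if sigma == 0:
        return float("nan")
    return float(np.mean(((x - mu) / sigma) ** 4) - 3.0)


def entropy(window) -> float:
    """Shannon entropy −Σ xᵢ² ln(xᵢ²) of the centred, unit-energy window (nats).

    Centring and normalising to Σxᵢ² = 1 makes xᵢ² a probability density, so
    the value is scale-invariant and bounded by ln N (uniform energy).
    0·ln 0 is taken as 0; an all-constant window → NaN.
    """
    x = _samples(window)
    if len(x) < 1:
        raise DataError("entropy needs at least 1 sample")
    x = x - x.mean() if len(x) > 1 else x
    energy = float(np.sum(x**2))
    if energy == 0:
        return float("nan")
    p = x**2 / energy
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def perfusion_index(ac, dc, beat_p2t=None) -> float:
    """Perfusion index PI = 100 · AC amplitude / DC level (%).

    The AC amplitude is the median per-beat peak-to-trough within the window
    when at least two are available, else the sine-equivalent 2√2·RMS
    fallback.  Non-positive DC → error.
    """
    ac = np.asarray(ac, dtype=float)
    dc_mean = float(np.mean(np.asarray(dc, dtype=float)))
    if dc_mean <= 0:
        raise DataError("non-positive DC level")
    if beat_p2t is not None and len(beat_p2t) >= 2:
        amp = float(np.median(beat_p2t))
    else:
        amp = float(2.0 * np.sqrt(2.0) * np.std(ac))
    return 100.0 * amp / dc_mean


def omega(components: ChannelComponents) -> float:
    """Ratio of ratios Ω = (AC_R/DC_R)/(AC_IR/DC_IR); zero AC_IR → NaN."""
    if components.ac_ir == 0:
        return float("nan")
    return (components.ac_r / components.dc_r) / (components.ac_ir / components.dc_ir)


def quality_indicator(
    window,
    fs: float,
    f0_hz: float,
    band: tuple[float, float] = (0.5, 40.0),
    half_width: float = 0.15,
) -> float:
    """Spectral-dominance quality score in [0, 100].

    100 × (power within ±``half_width`` Hz of the pulse fundamental and its
    first harmonic) / (total power in ``band``), on the linearly detrended
    window.  The unpadded rectangular periodogram is used because its bins
    partition the window power exactly (Parseval), so a periodic pulse train
    aligned with the window scores close to 100.  Missing pulse-rate
    estimate → NaN.
    """
    x = _samples(window)
    if len(x) < 4 * fs:
        raise DataError("QI needs a window of at least 4 s")
    if not np.isfinite(f0_hz) or f0_hz <= 0:
        return float("nan")
    x = sps.detrend(x, type="linear")
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    power = np.abs(np.fft.rfft(x)) ** 2
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    den = float(power[in_band].sum())
    if den <= 0:
        return float("nan")
    num_mask = in_band & (
        (np.abs(freqs - f0_hz) <= half_width) | (np.abs(freqs - 2.0 * f0_hz) <= half_width)
    )
    qi = 100.0 * float(power[num_mask].sum()) / den
    return float(np.clip(qi, 0.0, 100.0))


def validate_beats(
    ac_pulse: np.ndarray,
    beats: BeatSeries,
    fs: float,
    ibi_range_ms: tuple[float, float] = (300.0, 2000.0),
    ibi_tol: float = 0.30,
    corr_min: float = 0.80,
    template_len: int = 60,
) -> np.ndarray:
    """Per-beat validity flags (physiology, rhythm continuity, morphology).

    A beat is valid iff (a) its inter-beat interval lies in ``ibi_range_ms``,
    (b) the interval is within ±``ibi_tol`` of the running median of the last
    8 intervals, and (c) its waveform correlates ≥ ``corr_min`` with the
    running template (mean of the last 8 valid beats, resampled to a common
    length).  Until a template exists, the morphology test passes vacuously.
    """
    ac_pulse = np.asarray(ac_pulse, dtype=float)
    times = beats.peak_times
    n = len(times)
    flags = np.zeros(n, dtype=bool)
    if n == 0:
        return flags
    ibis = np.diff(times) * 1000.0
    recent_ibis: deque = deque(maxlen=8)
    templates: deque = deque(maxlen=8)
    grid = np.linspace(0.0, 1.0, template_len)
    for k, tau in enumerate(times):
        ibi = ibis[k - 1] if k > 0 else (ibis[0] if len(ibis) else 1000.0)
        ok = ibi_range_ms[0] <= ibi <= ibi_range_ms[1]
        if ok and recent_ibis:
            med = float(np.median(recent_ibis))
            ok = abs(ibi - med) <= ibi_tol * med
        wave = None
        if ok:
            lo = int((tau - 0.3 * ibi / 1000.0) * fs)
            hi = int((tau + 0.7 * ibi / 1000.0) * fs)
            if 0 <= lo < hi <= len(ac_pulse) and hi - lo > 3:
                seg = ac_pulse[lo:hi]
                wave = np.interp(grid, np.linspace(0, 1, len(seg)), seg)
                sd = wave.std()
                if sd > 0:
                    wave = (wave - wave.mean()) / sd
                else:
                    wave = None
            if wave is None:
                ok = False
        if ok and templates:
            template = np.mean(templates, axis=0)
            tsd = template.std()
            if tsd > 0:
                corr = float(np.mean(wave * (template - template.mean()) / tsd))
                ok = corr >= corr_min
        flags[k] = ok
        recent_ibis.append(ibi)
        if ok and wave is not None:
            templates.append(wave)
    return flags


def valid_pulse_detection(ac_pulse: np.ndarray, beats: BeatSeries, fs: float) -> float:
    """Percentage of detected beats passing the validity checks (0 if no beats)."""
    if len(beats) == 0:
        return 0.0
    flags = validate_beats(ac_pulse, beats, fs)
    return 100.0 * float(np.mean(flags))


def extract_sqi_series(record: PPGRecord, cfg: SQIWindowConfig | None = None) -> SQISeries:
    """Slide the 5-s window at 0.2 Hz and compute all indices per window.

    Skewness, entropy, kurtosis, PI and VPD are computed on both channels;
    Ω and QI once (QI on infrared, fundamental from the running pulse-rate
    estimate).  Windows where an index is undefined propagate NaN.
    """
    cfg = cfg or SQIWindowConfig()
    if record.duration < 30.0:
        raise DataError("record must be at least 30 s for SQI extraction")
    fs = record.fs
    ac_ir, dc_ir, ac_r, dc_r = decompose_ac_dc(record, cfg)
    pulse_ir = -ac_ir
    pulse_r = -ac_r
    beats = detect_beats(pulse_ir, fs)
    flags_ir = validate_beats(pulse_ir, beats, fs)
    flags_r = validate_beats(pulse_r, beats, fs)
    amps = beat_amplitudes(
        pulse_ir, beats, fs, channels={"ir": pulse_ir, "r": pulse_r},
        dc={"ir": dc_ir, "r": dc_r},
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        beat_ratio = (amps["r"] / amps["dc_r"]) / (amps["ir"] / amps["dc_ir"])
    t_pr, pr = pulse_rate(record)

    step = 1.0 / cfg.out_rate_hz
    t_end = record.duration - 1.0 / fs
    n_win = max(int(np.ceil(t_end / step - 1e-9)), 0)
    grid = cfg.window_s + step * np.arange(n_win)
    grid = grid[grid - cfg.window_s < t_end + 1e-9]

    cols: dict[str, np.ndarray] = {name: np.full(len(grid), np.nan) for name in SQI_COLUMNS}
    bt = amps["t"]
    beat_times = beats.peak_times
    for i, tk in enumerate(grid):
        lo = max(int(round((tk - cfg.window_s) * fs)), 0)
        hi = min(int(round(tk * fs)), len(record))
        if hi - lo < 4:
            continue
        w_ir = ac_ir[lo:hi]
        w_r = ac_r[lo:hi]
        cols["skewness_ir"][i] = skewness(w_ir)
        cols["skewness_r"][i] = skewness(w_r)
        cols["kurtosis_ir"][i] = kurtosis(w_ir)
        cols["kurtosis_r"][i] = kurtosis(w_r)
        cols["entropy_ir"][i] = entropy(w_ir)
        cols["entropy_r"][i] = entropy(w_r)
        in_amp = (bt > tk - cfg.window_s) & (bt <= tk)
        cols["pi_ir"][i] = perfusion_index(w_ir, dc_ir[lo:hi], amps["ir"][in_amp])
        cols["pi_r"][i] = perfusion_index(w_r, dc_r[lo:hi], amps["r"][in_amp])
        ratios = beat_ratio[in_amp]
        ratios = ratios[np.isfinite(ratios)]
        if len(ratios) >= 2:
            cols["omega"][i] = float(np.median(ratios))
        j = np.searchsorted(t_pr, tk + 1e-9) - 1
        f0 = pr[j] / 60.0 if 0 <= j < len(pr) and np.isfinite(pr[j]) else float("nan")
        cols["qi"][i] = quality_indicator(record.ir[lo:hi], fs, f0)
        in_beat = (beat_times > tk - cfg.window_s) & (beat_times <= tk)
        if np.any(in_beat):
            cols["vpd_ir"][i] = 100.0 * float(np.mean(flags_ir[in_beat]))
            cols["vpd_r"][i] = 100.0 * float(np.mean(flags_r[in_beat]))
        else:
            cols["vpd_ir"][i] = 0.0
            cols["vpd_r"][i] = 0.0
    return SQISeries(t=grid, values=cols)
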
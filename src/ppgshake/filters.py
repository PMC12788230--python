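"""Low-level filtering and beat-amplitude helpers shared by SQI and vitals stages.

The AC/DC split follows standard pulse-oximetry practice: the DC level is a
zero-phase low-pass at 0.4 Hz; the pulsatile AC component is a zero-phase
band-pass over the pulse band (default 0.5–10 Hz), which by design attenuates
rotor-harmonic vibration artifacts (> 20 Hz) by well over 20 dB.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import signal

from .exceptions import DataError
from .types import BeatSeries


@lru_cache(maxsize=64)
def _butter_sos(order: int, lo: float, hi: float | None, fs: float, btype: str):
    if btype == "band":
        wn = (lo, hi)
    else:
        wn = lo
    return signal.butter(order, wn, btype=btype, fs=fs, output="sos")


def lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 4) -> np.ndarray:
    sos = _butter_sos(order, cutoff, None, fs, "lowpass")
    return signal.sosfiltfilt(sos, x)


def bandpass(x: np.ndarray, fs: float, band: tuple[float, float], order: int = 4) -> np.ndarray:
    sos = _butter_sos(order, band[0], band[1], fs, "band")
    return signal.sosfiltfilt(sos, x)


def decompose_channel(
    x: np.ndarray,
    fs: float,
    dc_cutoff: float = 0.4,
    pulse_band: tuple[float, float] = (0.5, 10.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Split one raw optical channel into (ac, dc).

    Requires at least ``2·fs/dc_cutoff`` samples for filter warm-up; edge
    effects are confined to about one settling length at each end.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2 * fs / dc_cutoff:
        raise DataError(
            f"record too short for AC/DC decomposition: need ≥ {2 * fs / dc_cutoff:.0f} samples"
        )
    dc = lowpass(x, fs, dc_cutoff)
    ac = bandpass(x, fs, pulse_band)
    return ac, dc


def smooth(x: np.ndarray, fs: float, width_s: float = 0.05) -> np.ndarray:
    """Short moving-average smoothing used before reading beat extrema."""
    n = max(int(round(width_s * fs)), 1)
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def beat_amplitudes(
    ac_anchor: np.ndarray,
    beats: BeatSeries,
    fs: float,
    channels: dict[str, np.ndarray],
    dc: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Per-beat peak-to-trough amplitudes, read at common anchor indices.

    Peak and trough indices are located on a lightly smoothed anchor channel
    (the IR AC signal): the peak inside ±0.2·IBI of the beat time and the
    trough in the preceding half inter-beat interval.  All channels are then
    read at the *same* indices so the red/infrared amplitude ratio is not
    biased by channel-specific noise extremes.

    Returns a dict with ``"t"`` (beat times used), one amplitude array per
    channel, and — when ``dc`` is given — one ``dc_<name>`` level per channel.
    """
    anchor = smooth(np.asarray(ac_anchor, dtype=float), fs)
    smoothed = {name: smooth(np.asarray(ch, dtype=float), fs) for name, ch in channels.items()}
    n = len(anchor)
    times = beats.peak_times
    ibis_s = np.diff(times)
    out: dict[str, list] = {name: [] for name in channels}
    dc_out: dict[str, list] = {name: [] for name in (dc or {})}
    used_t = []
    for k, tau in enumerate(times):
        # representative local IBI (s): previous interval, else next, else 1 s
        if k > 0:
            ibi = ibis_s[k - 1]
        elif len(ibis_s):
            ibi = ibis_s[0]
        else:
            ibi = 1.0
        c = int(round(tau * fs))
        half = int(round(0.2 * ibi * fs))
        p_lo, p_hi = max(c - half, 0), min(c + half + 1, n)
        if p_hi - p_lo < 2:
            continue
        pk = p_lo + int(np.argmax(anchor[p_lo:p_hi]))
        t_lo = max(pk - int(round(0.55 * ibi * fs)), 0)
        if pk - t_lo < 2:
            continue
        tr = t_lo + int(np.argmin(anchor[t_lo:pk]))
        used_t.append(tau)
        for name in channels:
            out[name].append(smoothed[name][pk] - smoothed[name][tr])
        for name in dc_out:
            dc_out[name].append(np.asarray(dc[name], dtype=float)[pk])
    result = {"t": np.asarray(used_t)}
    for name in channels:
        result[name] = np.asarray(out[name])
    for name in dc_out:
        result[f"dc_{name}"] = np.asarray(dc_out[name])
    return result
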
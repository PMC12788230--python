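"""Core domain containers for two-wavelength in-ear PPG analysis.

All time axes are seconds from recording start (t0 = 0 unless stated), double
precision.  PPG samples are optical intensities in arbitrary units (a.u.);
acceleration is in g.  Missing values are explicit NaNs and are never silently
dropped — study-level statistics skip them with a logged count.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DataError, ParameterError

#: Protocol phases: seated at rest vs. exposed to simulated cabin vibration.
PHASES = ("no_flight", "in_flight")

#: Accelerometer mounting sites.
LOCATIONS = ("seat", "head")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DataError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class PPGRecord:
    """Uniformly sampled two-channel (red 655 nm, infrared 940 nm) optical series."""

    red: np.ndarray
    ir: np.ndarray
    fs: float = 200.0
    t0: float = 0.0
    phase: str = "no_flight"
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.red = _as_float_array(self.red, "red")
        self.ir = _as_float_array(self.ir, "ir")
        if len(self.red) != len(self.ir):
            raise DataError("red and ir channels must have equal length")
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if self.phase not in PHASES:
            raise ParameterError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if len(self.red) and not (np.isfinite(self.red).all() and np.isfinite(self.ir).all()):
            raise DataError("PPG samples must be finite")

    def __len__(self) -> int:
        return len(self.ir)

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(len(self.ir)) / self.fs

    @property
    def duration(self) -> float:
        return len(self.ir) / self.fs


@dataclass
class AccelRecord:
    """Tri-axial acceleration series in g (±16 g range, default 400 Hz)."""

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float = 400.0
    t0: float = 0.0
    location: str = "seat"
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.ax = _as_float_array(self.ax, "ax")
        self.ay = _as_float_array(self.ay, "ay")
        self.az = _as_float_array(self.az, "az")
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise DataError("accelerometer axes must have equal length")
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if self.location not in LOCATIONS:
            raise ParameterError(f"location must be one of {LOCATIONS}")
        for name, axis in (("ax", self.ax), ("ay", self.ay), ("az", self.az)):
            if len(axis) and np.nanmax(np.abs(axis)) > 16.0 + 1e-9:
                raise DataError(f"{name} exceeds the ±16 g sensor range")

    def __len__(self) -> int:
        return len(self.az)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.az)) / self.fs

    def magnitude(self) -> np.ndarray:
        """Euclidean magnitude sqrt(ax² + ay² + az²)."""
        return np.sqrt(self.ax**2 + self.ay**2 + self.az**2)


@dataclass
class BeatSeries:
    """Detected (or ground-truth) pulse peaks with inter-beat intervals in ms."""

    peak_times: np.ndarray
    valid_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.peak_times = _as_float_array(self.peak_times, "peak_times")
        if len(self.peak_times) > 1 and np.any(np.diff(self.peak_times) <= 0):
            raise DataError("peak_times must be strictly increasing")
        if self.valid_flags is None:
            self.valid_flags = np.ones(len(self.peak_times), dtype=bool)
        else:
            self.valid_flags = np.asarray(self.valid_flags, dtype=bool)
            if len(self.valid_flags) != len(self.peak_times):
                raise DataError("valid_flags must have one entry per beat")

    def __len__(self) -> int:
        return len(self.peak_times)

    @property
    def ibis(self) -> np.ndarray:
        """Inter-beat intervals in milliseconds; ibis[i] = peaks[i+1] − peaks[i]."""
        return np.diff(self.peak_times) * 1000.0


@dataclass
class SignalWindow:
    """A finite windowed signal with cached population (1/N) moments."""

    samples: np.ndarray
    N: int = field(init=False)
    mu_hat: float = field(init=False)
    sigma_hat: float = field(init=False)

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples, "samples")
        if not np.isfinite(self.samples).all():
            raise DataError("window samples must be finite")
        self.N = len(self.samples)
        self.mu_hat = float(np.mean(self.samples)) if self.N else float("nan")
        # population (1/N) standard deviation, matching the printed moment formulas
        self.sigma_hat = float(np.std(self.samples)) if self.N else float("nan")


@dataclass
class ChannelComponents:
    """Beat- or window-wise AC amplitudes and DC levels for both wavelengths."""

    ac_r: float
    dc_r: float
    ac_ir: float
    dc_ir: float

    def __post_init__(self) -> None:
        if not (self.dc_r > 0 and self.dc_ir > 0):
            raise DataError("DC levels must be positive")
        if self.ac_r < 0 or self.ac_ir < 0:
            raise DataError("AC amplitudes must be non-negative")


#: Column order of the eleven tested quality indices plus PI on the red channel.
SQI_COLUMNS = (
    "pi_ir",
    "pi_r",
    "skewness_ir",
    "skewness_r",
    "entropy_ir",
    "entropy_r",
    "kurtosis_ir",
    "kurtosis_r",
    "omega",
    "qi",
    "vpd_ir",
    "vpd_r",
)

#: The eleven indices entering the paired phase comparison (PI red is computed
#: but, like the published analysis, only PI IR is tested).
SQI_TEST_SET = (
    "omega",
    "pi_ir",
    "entropy_ir",
    "entropy_r",
    "kurtosis_ir",
    "kurtosis_r",
    "skewness_ir",
    "skewness_r",
    "qi",
    "vpd_ir",
    "vpd_r",
)


@dataclass
class SQISeries:
    """Per-window quality indices on the common 0.2 Hz grid."""

    t: np.ndarray
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        for name in SQI_COLUMNS:
            if name not in self.values:
                raise DataError(f"SQISeries is missing column {name!r}")
            col = _as_float_array(self.values[name], name)
            if len(col) != len(self.t):
                raise DataError(f"column {name!r} does not share the time grid")
            self.values[name] = col
        qi = self.values["qi"]
        for name in ("qi", "vpd_ir", "vpd_r"):
            col = self.values[name]
            finite = col[np.isfinite(col)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 100 + 1e-9):
                raise DataError(f"{name} must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.t)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, **{k: self.values[k] for k in SQI_COLUMNS}})


@dataclass
class VitalsSeries:
    """In-ear and reference vitals on the 30-s comparison grid, with per-point bias."""

    t: np.ndarray
    pr_ear: np.ndarray
    spo2_ear: np.ndarray
    hr_ref: np.ndarray
    spo2_ref: np.ndarray

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        n = len(self.t)
        for name in ("pr_ear", "spo2_ear", "hr_ref", "spo2_ref"):
            col = _as_float_array(getattr(self, name), name)
            if len(col) != n:
                raise DataError(f"{name} does not share the time grid")
            setattr(self, name, col)
        for name in ("spo2_ear", "spo2_ref"):
            col = getattr(self, name)
            finite = col[np.isfinite(col)]
            if finite.size and (finite.min() < 50 - 1e-9 or finite.max() > 100 + 1e-9):
                raise DataError(f"{name} outside the plausible 50–100% range")
        for name in ("pr_ear", "hr_ref"):
            col = getattr(self, name)
            finite = col[np.isfinite(col)]
            if finite.size and (finite.min() < 20 or finite.max() > 250):
                raise DataError(f"{name} outside the plausible 20–250 bpm range")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def bias_pr(self) -> np.ndarray:
        """Pulse-rate bias, in-ear minus reference (bpm)."""
        return self.pr_ear - self.hr_ref

    @property
    def bias_spo2(self) -> np.ndarray:
        """SpO₂ bias, in-ear minus reference (%)."""
        return self.spo2_ear - self.spo2_ref

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "pr_ear": self.pr_ear,
                "spo2_ear": self.spo2_ear,
                "hr_ref": self.hr_ref,
                "spo2_ref": self.spo2_ref,
            }
        )


@dataclass
class ReferenceVitals:
    """Emulated clinical-monitor vitals at 1 Hz (trimmed R-R HR, 8-s-mean SpO₂)."""

    t: np.ndarray
    hr_ref: np.ndarray
    spo2_ref: np.ndarray

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        self.hr_ref = _as_float_array(self.hr_ref, "hr_ref")
        self.spo2_ref = _as_float_array(self.spo2_ref, "spo2_ref")
        if not (len(self.t) == len(self.hr_ref) == len(self.spo2_ref)):
            raise DataError("reference vitals columns must share the time grid")

    def __len__(self) -> int:
        return len(self.t)
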
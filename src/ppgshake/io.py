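"""CSV readers/writers and the two resampling rules shared by every stage.

CSV schemas (UTF-8, comma-separated, '.' decimal):

* PPG:    ``t,red,ir,phase,subject_id``
* accel:  ``t,ax,ay,az,location,subject_id``
* vitals: ``t,pr_ear,spo2_ear,hr_ref,spo2_ref``

Both resamplers use trailing, half-open windows ``(t − w, t]``: every output
value depends only on inputs at or before its timestamp, matching an online
monitor.  Windows without any (non-missing) input yield NaN.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError, SchemaError
from .types import AccelRecord, PPGRecord, VitalsSeries

_PPG_COLUMNS = ["t", "red", "ir", "phase", "subject_id"]
_ACCEL_COLUMNS = ["t", "ax", "ay", "az", "location", "subject_id"]
_VITALS_COLUMNS = ["t", "pr_ear", "spo2_ear", "hr_ref", "spo2_ref"]

_SCHEMAS = {"ppg": _PPG_COLUMNS, "accel": _ACCEL_COLUMNS, "vitals": _VITALS_COLUMNS}

#: tolerance on uniform sample spacing for ppg/accel time columns (seconds)
_UNIFORM_TOL = 1e-6


def _check_columns(df: pd.DataFrame, schema: str) -> None:
    expected = _SCHEMAS[schema]
    for col in expected:
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} for schema {schema!r}")


def _check_signal_finite(df: pd.DataFrame, cols: list[str]) -> None:
    for col in cols:
        bad = np.flatnonzero(~np.isfinite(df[col].to_numpy(dtype=float)))
        if bad.size:
            raise DataError(f"NaN or non-finite value in column {col!r} at row {bad[0]}")


def _uniform_fs(t: np.ndarray) -> float:
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise DataError("time column must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > _UNIFORM_TOL:
            raise DataError("time column is not uniformly spaced within 1e-6 s")
        return 1.0 / dt[0]
    return float("nan")


def read_timeseries_csv(path: str | os.PathLike, schema: str):
    """Read a typed time-series CSV.

    Parameters
    ----------
    path : path to an existing CSV file
    schema : one of ``"ppg"``, ``"accel"``, ``"vitals"``

    Returns
    -------
    PPGRecord, AccelRecord or VitalsSeries according to ``schema``.
    """
    if schema not in _SCHEMAS:
        raise ParameterError(f"unknown schema {schema!r}")
    df = pd.read_csv(path)
    _check_columns(df, schema)
    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise DataError("time column must be strictly increasing")

    if schema == "ppg":
        _check_signal_finite(df, ["red", "ir"])
        fs = _uniform_fs(t)
        phase = str(df["phase"].iloc[0]) if len(df) else "no_flight"
        subject = str(df["subject_id"].iloc[0]) if len(df) else "S00"
        return PPGRecord(
            red=df["red"].to_numpy(dtype=float),
            ir=df["ir"].to_numpy(dtype=float),
            fs=fs if np.isfinite(fs) else 200.0,
            t0=float(t[0]) if len(t) else 0.0,
            phase=phase,
            subject_id=subject,
        )
    if schema == "accel":
        _check_signal_finite(df, ["ax", "ay", "az"])
        fs = _uniform_fs(t)
        location = str(df["location"].iloc[0]) if len(df) else "seat"
        subject = str(df["subject_id"].iloc[0]) if len(df) else "S00"
        return AccelRecord(
            ax=df["ax"].to_numpy(dtype=float),
            ay=df["ay"].to_numpy(dtype=float),
            az=df["az"].to_numpy(dtype=float),
            fs=fs if np.isfinite(fs) else 400.0,
            t0=float(t[0]) if len(t) else 0.0,
            location=location,
            subject_id=subject,
        )
    # vitals: non-uniform grids allowed, NaNs are legitimate missings
    return VitalsSeries(
        t=t,
        pr_ear=df["pr_ear"].to_numpy(dtype=float),
        spo2_ear=df["spo2_ear"].to_numpy(dtype=float),
        hr_ref=df["hr_ref"].to_numpy(dtype=float),
        spo2_ref=df["spo2_ref"].to_numpy(dtype=float),
    )


def write_timeseries_csv(record, path: str | os.PathLike) -> str:
    """Write a record to CSV with repr round-trip float precision.

    Column order is deterministic (see module docstring).  Returns ``path``.
    """
    if isinstance(record, PPGRecord):
        df = pd.DataFrame(
            {
                "t": record.t,
                "red": record.red,
                "ir": record.ir,
                "phase": record.phase,
                "subject_id": record.subject_id,
            },
            columns=_PPG_COLUMNS,
        )
    elif isinstance(record, AccelRecord):
        df = pd.DataFrame(
            {
                "t": record.t,
                "ax": record.ax,
                "ay": record.ay,
                "az": record.az,
                "location": record.location,
                "subject_id": record.subject_id,
            },
            columns=_ACCEL_COLUMNS,
        )
    elif isinstance(record, VitalsSeries):
        df = record.to_frame()[_VITALS_COLUMNS]
    else:
        raise ParameterError(f"cannot serialise object of type {type(record).__name__}")
    try:
        # pandas stringifies float64 via repr, which round-trips exactly
        df.to_csv(path, index=False)
    except OSError as exc:  # unwritable path
        raise DataError(f"cannot write {path}: {exc}") from exc
    return str(path)


def _trailing_window_means(
    t: np.ndarray, x: np.ndarray, grid: np.ndarray, window_s: float
) -> np.ndarray:
    """Mean of x over (g − window_s, g] for each grid point g; empty → NaN."""
    lo = np.searchsorted(t, grid - window_s + 1e-12, side="left")
    hi = np.searchsorted(t, grid + 1e-12, side="right")
    finite = np.isfinite(x)
    csum = np.concatenate([[0.0], np.cumsum(np.where(finite, x, 0.0))])
    cnt = np.concatenate([[0], np.cumsum(finite.astype(int))])
    counts = cnt[hi] - cnt[lo]
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, (csum[hi] - csum[lo]) / np.maximum(counts, 1), np.nan)
    return out


def _trailing_grid(t0: float, t_end: float, start_offset: float, step: float) -> np.ndarray:
    """Grid t0+start_offset, +step, ... while the trailing window still overlaps data."""
    # a grid point tk is emitted while tk − start_offset < t_end (window not empty-by-
    # construction); equality excluded up to float fuzz
    n = int(np.ceil((t_end - t0) / step - 1e-9))
    n = max(n, 0)
    return t0 + start_offset + step * np.arange(n)


def moving_average_resample(
    t, x, window_s: float = 5.0, out_rate_hz: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a timestamped series by a trailing moving average.

    The output grid starts at ``t[0] + window_s`` and steps by ``1/out_rate_hz``;
    each value is the arithmetic mean over the half-open window ``(t − w, t]``.

    Returns ``(t_out, y_out)``; empty input gives empty output.
    """
    if out_rate_hz <= 0:
        raise ParameterError("out_rate_hz must be positive")
    if window_s <= 0:
        raise ParameterError("window_s must be positive")
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size == 0:
        return np.array([]), np.array([])
    if np.any(np.diff(t) < 0):
        raise DataError("input timestamps must be ascending")
    step = 1.0 / out_rate_hz
    grid = _trailing_grid(float(t[0]), float(t[-1]), window_s, step)
    # the grid is anchored at t0 + window_s, so shift the overlap criterion:
    grid = grid[grid - window_s < t[-1] + 1e-9]
    return grid, _trailing_window_means(t, x, grid, window_s)


def vitals_sample(
    t, x, step_s: float = 30.0, pre_window_s: float = 8.0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a series every ``step_s`` seconds, averaging the preceding window.

    Output instants are absolute multiples of ``step_s`` (t = step, 2·step, …,
    from the recording origin); each value is the mean over the trailing
    half-open window ``(t − pre_window_s, t]``.  Windows without input yield NaN.
    """
    if step_s <= 0 or pre_window_s <= 0:
        raise ParameterError("step_s and pre_window_s must be positive")
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size == 0:
        return np.array([]), np.array([])
    if np.any(np.diff(t) < 0):
        raise DataError("input timestamps must be ascending")
    k_first = max(int(np.floor(float(t[0]) / step_s + 1e-9)) + 1, 1)
    k_last = int(np.ceil((float(t[-1]) + pre_window_s) / step_s - 1e-9))
    grid = step_s * np.arange(k_first, max(k_last, k_first - 1) + 1)
    grid = grid[grid - pre_window_s < t[-1] + 1e-9]
    return grid, _trailing_window_means(t, x, grid, pre_window_s)
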
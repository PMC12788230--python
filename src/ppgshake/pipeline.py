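"""End-to-end in-silico study: simulate, extract, compare, report.

``run_study`` reproduces the full analysis chain on a synthetic cohort:
generate both protocol phases per subject, extract the 0.2 Hz SQI series and
the 1 Hz vitals, build the 30-s comparison grid against the emulated clinical
reference, run the normality-gated paired phase comparisons for the eleven
quality indices and the two bias series, compute Bland–Altman and Lin's CCC
agreement per vital sign and phase, and detect rotor-harmonic artifact peaks
per subject.  The report is a pure function of the configuration, including
its master seed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, SubjectData, VibrationProfile, generate_cohort
from .exceptions import DataError, ParameterError, PipelineError
from .spectral import accel_spectrum, compare_phase_spectra, compute_spectrum, find_artifact_peaks
from .sqi import SQIWindowConfig, extract_sqi_series
from .stats import AgreementResult, PairedTestResult, agreement, test_sqi_phase_difference
from .types import SQI_TEST_SET, VitalsSeries
from .vitals import CalibrationCurve, PRConfig, build_vitals_series, pulse_rate, spo2

logger = logging.getLogger(__name__)

PHASES = ("no_flight", "in_flight")

#: printed labels for the eleven tested indices (report tables)
SQI_LABELS = {
    "omega": "Omega",
    "pi_ir": "PI IR",
    "entropy_ir": "Entropy IR",
    "entropy_r": "Entropy R",
    "kurtosis_ir": "Kurtosis IR",
    "kurtosis_r": "Kurtosis R",
    "skewness_ir": "Skewness IR",
    "skewness_r": "Skewness R",
    "qi": "QI",
    "vpd_ir": "VPD IR",
    "vpd_r": "VPD R",
}


@dataclass
class StudyConfig:
    """Configuration of the full in-silico study."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    vibration: VibrationProfile = field(default_factory=VibrationProfile)
    pr: PRConfig = field(default_factory=PRConfig)
    calibration: CalibrationCurve = field(default_factory=CalibrationCurve)
    sqi: SQIWindowConfig = field(default_factory=SQIWindowConfig)
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        def build(klass, key):
            section = dict(raw.get(key) or {})
            for name, value in section.items():
                if isinstance(value, list):
                    section[name] = tuple(value)
            return klass(**section)

        return cls(
            cohort=build(CohortConfig, "cohort"),
            vibration=build(VibrationProfile, "vibration"),
            pr=build(PRConfig, "pr"),
            calibration=build(CalibrationCurve, "calibration"),
            sqi=build(SQIWindowConfig, "sqi"),
            alpha=float(raw.get("alpha", 0.05)),
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


@dataclass
class StudyReport:
    """Structured study outcome; JSON-serialisable and seed-reproducible."""

    config: dict
    version: str
    sqi_tests: dict[str, PairedTestResult]
    sqi_phase_stats: dict[str, dict[str, tuple[float, float]]]
    sqi_subject_means: dict[str, dict[str, list[float]]]
    bias_tests: dict[str, PairedTestResult]
    agreement: dict[str, dict[str, AgreementResult]]
    spectral: dict[str, dict]
    missing_counts: dict[str, int]
    vitals: dict[str, dict[str, "pd.DataFrame"]] = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return clean(dataclasses.asdict(obj))
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return [clean(v) for v in obj.tolist()]
            if isinstance(obj, (np.floating, float)):
                v = float(obj)
                return v if np.isfinite(v) else None
            if isinstance(obj, np.integer):
                return int(obj)
            return obj

        return {
            "config": clean(self.config),
            "version": self.version,
            "sqi_tests": clean(self.sqi_tests),
            "sqi_phase_stats": clean(self.sqi_phase_stats),
            "sqi_subject_means": clean(self.sqi_subject_means),
            "bias_tests": clean(self.bias_tests),
            "agreement": clean(self.agreement),
            "spectral": clean(self.spectral),
            "missing_counts": clean(self.missing_counts),
            "n_sqi_tests_uncorrected": len(self.sqi_tests),
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _stage(stage: str, subject: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {stage!r} failed for subject {subject}: {exc}") from exc
            return False

    return _Ctx()


def _subject_vitals(data: SubjectData, phase: str, config: StudyConfig) -> VitalsSeries:
    record = data.ppg[phase]
    t_pr, pr = pulse_rate(record, config.pr)
    t_sp, sp = spo2(record, config.calibration, window_s=config.sqi.window_s)
    return build_vitals_series(t_pr, pr, t_sp, sp, data.ref[phase])


def run_study(config: StudyConfig | str | os.PathLike | None = None, out_dir=None) -> StudyReport:
    """Execute the full pipeline and return (optionally write) the report."""
    if config is None:
        config = StudyConfig()
    elif not isinstance(config, StudyConfig):
        config = StudyConfig.from_yaml(config)

    subjects = generate_cohort(config.cohort, config.vibration)

    sqi_means: dict[str, dict[str, list[float]]] = {
        name: {phase: [] for phase in PHASES} for name in SQI_TEST_SET
    }
    vitals: dict[str, dict[str, VitalsSeries]] = {}
    spectral: dict[str, dict] = {}
    missing = {"sqi_windows": 0, "vitals_points": 0}

    for data in subjects:
        sid = data.params.subject_id
        vitals[sid] = {}
        for phase in PHASES:
            with _stage("sqi_extraction", sid):
                series = extract_sqi_series(data.ppg[phase], config.sqi)
                for name in SQI_TEST_SET:
                    col = series[name]
                    missing["sqi_windows"] += int(np.sum(~np.isfinite(col)))
                    sqi_means[name][phase].append(float(np.nanmean(col)))
            with _stage("vitals_extraction", sid):
                vs = _subject_vitals(data, phase, config)
                missing["vitals_points"] += int(
                    np.sum(~np.isfinite(vs.pr_ear)) + np.sum(~np.isfinite(vs.spo2_ear))
                )
                vitals[sid][phase] = vs
        with _stage("spectral_analysis", sid):
            acc_spec = accel_spectrum(data.accel["in_flight"])
            acc_peaks = find_artifact_peaks(acc_spec, fmin=10.0, n_peaks=2)
            spec_nf = compute_spectrum(data.ppg["no_flight"].ir, config.cohort.fs_ppg)
            spec_if = compute_spectrum(data.ppg["in_flight"].ir, config.cohort.fs_ppg)
            emergent = compare_phase_spectra(spec_nf, spec_if)
            spectral[sid] = {
                "accel_peaks_hz": [f for f, _ in acc_peaks],
                "ppg_emergent_peaks_hz": [f for f, _ in emergent],
            }

    sqi_tests: dict[str, PairedTestResult] = {}
    sqi_phase_stats: dict[str, dict[str, tuple[float, float]]] = {}
    for name in SQI_TEST_SET:
        nf = np.asarray(sqi_means[name]["no_flight"])
        fl = np.asarray(sqi_means[name]["in_flight"])
        with _stage("sqi_phase_test", name):
            sqi_tests[name] = test_sqi_phase_difference(nf, fl, alpha=config.alpha)
        sqi_phase_stats[name] = {
            "no_flight": (float(np.nanmean(nf)), float(np.nanstd(nf, ddof=1))),
            "in_flight": (float(np.nanmean(fl)), float(np.nanstd(fl, ddof=1))),
        }

    bias_tests: dict[str, PairedTestResult] = {}
    for key, attr in (("bias_pr", "bias_pr"), ("bias_spo2", "bias_spo2")):
        per_phase = {
            phase: [float(np.nanmean(getattr(vitals[sid][phase], attr))) for sid in vitals]
            for phase in PHASES
        }
        with _stage("bias_phase_test", key):
            bias_tests[key] = test_sqi_phase_difference(
                per_phase["no_flight"], per_phase["in_flight"], alpha=config.alpha
            )

    agreement_results: dict[str, dict[str, AgreementResult]] = {"pr": {}, "spo2": {}}
    for phase in PHASES:
        ear_pr = np.concatenate([vitals[sid][phase].pr_ear for sid in vitals])
        ref_hr = np.concatenate([vitals[sid][phase].hr_ref for sid in vitals])
        ear_sp = np.concatenate([vitals[sid][phase].spo2_ear for sid in vitals])
        ref_sp = np.concatenate([vitals[sid][phase].spo2_ref for sid in vitals])
        with _stage("agreement", phase):
            agreement_results["pr"][phase] = agreement(ear_pr, ref_hr)
            agreement_results["spo2"][phase] = agreement(ear_sp, ref_sp)

    report = StudyReport(
        config={
            "cohort": dataclasses.asdict(config.cohort),
            "vibration": dataclasses.asdict(config.vibration),
            "pr": dataclasses.asdict(config.pr),
            "calibration": dataclasses.asdict(config.calibration),
            "sqi": dataclasses.asdict(config.sqi),
            "alpha": config.alpha,
        },
        version=__version__,
        sqi_tests=sqi_tests,
        sqi_phase_stats=sqi_phase_stats,
        sqi_subject_means={
            name: {phase: list(vals) for phase, vals in by_phase.items()}
            for name, by_phase in sqi_means.items()
        },
        bias_tests=bias_tests,
        agreement=agreement_results,
        spectral=spectral,
        missing_counts=missing,
        vitals={sid: {ph: vitals[sid][ph].to_frame() for ph in PHASES} for sid in vitals},
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        report.to_json(os.path.join(out_dir, "report.json"))
        render_tables(report, os.path.join(out_dir, "tables"))
    return report


def render_tables(report: StudyReport, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the four result tables as CSVs; returns {table name: path}.

    Shapes: normality (W, p per SQI); paired-t results; Wilcoxon results;
    agreement (Difference, LoA bounds and CCC per vital sign per phase).
    Values are written at full precision so a parsed table equals the report.
    """
    if not report.sqi_tests:
        raise DataError("cannot render tables from an empty report")
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    rows = []
    for name, res in report.sqi_tests.items():
        rows.append(
            {"Parameter": SQI_LABELS[name], "W": res.normality_W, "p_value": res.normality_p}
        )
    paths["normality"] = os.path.join(out_dir, "table1_shapiro.csv")
    pd.DataFrame(rows).to_csv(paths["normality"], index=False)

    t_rows, w_rows = [], []
    for name, res in report.sqi_tests.items():
        stats = report.sqi_phase_stats[name]
        base = {
            "Parameter": SQI_LABELS[name],
            "no_flight_mean": stats["no_flight"][0],
            "no_flight_sd": stats["no_flight"][1],
            "in_flight_mean": stats["in_flight"][0],
            "in_flight_sd": stats["in_flight"][1],
        }
        if res.test == "paired_t":
            t_rows.append({**base, "df": res.df, "t": res.statistic, "p_value": res.p})
        else:
            w_rows.append({**base, "V": res.statistic, "z": res.z, "p_value": res.p})
    paths["paired_t"] = os.path.join(out_dir, "table2_paired_t.csv")
    pd.DataFrame(t_rows).to_csv(paths["paired_t"], index=False)
    paths["wilcoxon"] = os.path.join(out_dir, "table3_wilcoxon.csv")
    pd.DataFrame(w_rows).to_csv(paths["wilcoxon"], index=False)

    columns = {
        "PR_no_flight": report.agreement["pr"]["no_flight"],
        "PR_in_flight": report.agreement["pr"]["in_flight"],
        "SpO2_no_flight": report.agreement["spo2"]["no_flight"],
        "SpO2_in_flight": report.agreement["spo2"]["in_flight"],
    }
    table4 = pd.DataFrame(
        {
            name: [res.bias, res.loa_lower, res.loa_upper, res.ccc]
            for name, res in columns.items()
        },
        index=["Difference", "Lower LoA", "Upper LoA", "CCC"],
    )
    paths["agreement"] = os.path.join(out_dir, "table4_agreement.csv")
    table4.to_csv(paths["agreement"], index_label="Row")
    return paths
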
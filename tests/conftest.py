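"""Shared fixtures: small seeded cohorts and clean constructed records."""
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

import ppgshake as ps

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Four subjects, two minutes per phase — quick but long enough for SQIs."""
    return ps.CohortConfig(n_subjects=4, phase_duration_s=120.0, master_seed=0)


@pytest.fixture(scope="session")
def subject_params(small_cohort):
    return ps.sample_subject(small_cohort, 0)


@pytest.fixture(scope="session")
def clean_params(subject_params):
    """Same subject, noise switched off (for round-trip/recovery checks)."""
    return replace(subject_params, noise_sd=0.0, pert_sd=0.0)


@pytest.fixture(scope="session")
def clean_record(clean_params, small_cohort):
    beats = ps.synth_beats(clean_params, small_cohort.phase_duration_s)
    rec = ps.synth_ppg(clean_params, beats, None, small_cohort)
    return rec, beats


@pytest.fixture(scope="session")
def default_report():
    """Full default study (16 subjects × 2 × 10 min, master seed 0).

    Session-scoped because the run takes about half a minute; every test that
    needs the end-to-end result shares it.
    """
    return ps.run_study()
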
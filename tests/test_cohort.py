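"""Generator contracts: determinism, population targets, signal construction."""
from dataclasses import replace

import numpy as np
import pytest

import ppgshake as ps
from ppgshake.exceptions import ParameterError
from ppgshake.filters import bandpass


class TestSampleSubject:
    def test_deterministic_given_seed_and_index(self, small_cohort):
        a = ps.sample_subject(small_cohort, 1)
        b = ps.sample_subject(small_cohort, 1)
        assert a == b

    def test_distinct_seeds_across_cohort(self):
        cohort = ps.CohortConfig(n_subjects=16)
        seeds = {ps.sample_subject(cohort, i).seed for i in range(16)}
        assert len(seeds) == 16

    def test_population_heart_rate_target(self):
        # Monte-Carlo over 1000 subjects: empirical mean within 70 ± 1 bpm
        cohort = ps.CohortConfig(n_subjects=1000, master_seed=42)
        hrs = [ps.sample_subject(cohort, i).hr_mean for i in range(1000)]
        assert abs(np.mean(hrs) - 70.0) < 1.0
        spo2 = [ps.sample_subject(cohort, i).spo2_true for i in range(1000)]
        assert 96.0 < np.mean(spo2) < 97.0

    def test_perfusion_index_lognormal_median(self):
        cohort = ps.CohortConfig(n_subjects=1000, master_seed=3)
        pis = [ps.sample_subject(cohort, i).pi_target for i in range(1000)]
        assert abs(np.median(pis) - 1.0) < 0.1

    def test_index_out_of_range(self, small_cohort):
        with pytest.raises(ParameterError):
            ps.sample_subject(small_cohort, small_cohort.n_subjects)


class TestSynthBeats:
    def test_zero_variability_gives_constant_ibis(self, subject_params):
        p = replace(subject_params, hr_sd_within=0.0)
        beats = ps.synth_beats(p, 60.0)
        np.testing.assert_allclose(beats.ibis, 60000.0 / p.hr_mean, atol=1e-9)

    def test_beat_count_matches_rate(self, subject_params):
        p = replace(subject_params, hr_mean=60.0)
        beats = ps.synth_beats(p, 600.0)
        assert abs(len(beats) - 600) <= 3

    def test_mean_ibi_within_two_percent(self, subject_params):
        beats = ps.synth_beats(subject_params, 600.0)
        expected = 60000.0 / subject_params.hr_mean
        assert abs(beats.ibis.mean() - expected) / expected < 0.02

    def test_coverage_and_clipping(self, subject_params):
        beats = ps.synth_beats(subject_params, 120.0)
        assert beats.peak_times[-1] > 120.0
        assert beats.ibis.min() >= 300.0 and beats.ibis.max() <= 2000.0


class TestSynthPpg:
    def test_clean_signal_has_no_high_frequency_energy(self, clean_record, small_cohort):
        rec, _ = clean_record
        high = bandpass(rec.ir, rec.fs, (15.0, 60.0))
        pulse = bandpass(rec.ir, rec.fs, (0.5, 10.0))
        assert np.var(high) < 1e-4 * np.var(pulse)

    def test_omega_recovery_for_known_spo2(self, clean_params, small_cohort):
        # Ω measured by the ratio-of-ratios estimator should be (110−97)/25
        p = replace(clean_params, spo2_true=97.0)
        beats = ps.synth_beats(p, 120.0)
        rec = ps.synth_ppg(p, beats, None, small_cohort)
        series = ps.extract_sqi_series(rec)
        assert np.nanmean(series["omega"]) == pytest.approx(0.52, abs=0.02)

    def test_peak_to_trough_equals_pi_target(self, clean_params, small_cohort):
        p = replace(clean_params, pi_target=1.0, dc_ir=2.0)
        beats = ps.synth_beats(replace(p, hr_sd_within=0.0), 60.0)
        rec = ps.synth_ppg(p, beats, None, small_cohort)
        pulse = -bandpass(rec.ir, rec.fs, (0.5, 10.0))
        t = rec.t
        p2t = []
        for tau in beats.peak_times[3:-3]:
            sel = (t > tau - 0.5) & (t <= tau + 0.5)
            p2t.append(pulse[sel].max() - pulse[sel].min())
        assert np.median(p2t) == pytest.approx(0.02, rel=0.06)

    def test_incompatible_spo2_calibration_raises(self, clean_params, small_cohort):
        cohort = replace(small_cohort, calibration=(95.0, 25.0))
        p = replace(clean_params, spo2_true=96.0)  # Ω would be negative
        beats = ps.synth_beats(p, 60.0)
        with pytest.raises(ParameterError):
            ps.synth_ppg(p, beats, None, cohort)

    def test_spo2_round_trip_across_range(self, clean_params, small_cohort):
        # Ω round-trip: spo2_true in [90, 100] recovered within ±0.5%
        for spo2_true in (90.0, 93.0, 96.0, 99.0):
            p = replace(clean_params, spo2_true=spo2_true)
            beats = ps.synth_beats(p, 120.0)
            rec = ps.synth_ppg(p, beats, None, small_cohort)
            _, sp = ps.spo2(rec)
            assert np.nanmean(sp) == pytest.approx(spo2_true, abs=0.5)

    def test_pi_recovery_across_seeded_subjects(self):
        # measured PI within ±10% relative of pi_target on clean signals
        cohort = ps.CohortConfig(n_subjects=100, phase_duration_s=60.0, master_seed=9)
        errs = []
        for i in range(0, 100, 2):  # 50 subjects keep the check under a minute
            p = replace(ps.sample_subject(cohort, i), noise_sd=0.0, pert_sd=0.0)
            beats = ps.synth_beats(p, 60.0)
            rec = ps.synth_ppg(p, beats, None, cohort)
            ac, dc = ps.decompose_ac_dc(rec)[:2]
            from ppgshake.filters import beat_amplitudes
            from ppgshake.vitals import detect_beats

            det = detect_beats(-ac, rec.fs)
            amps = beat_amplitudes(-ac, det, rec.fs, channels={"ir": -ac})
            pi = 100.0 * np.median(amps["ir"]) / dc.mean()
            errs.append(pi / p.pi_target - 1.0)
        assert np.max(np.abs(errs)) < 0.10

    def test_artifact_additivity(self, clean_params, small_cohort):
        # in-flight minus no-flight (same seed) contains only the injected tones
        profile = ps.VibrationProfile()
        beats = ps.synth_beats(clean_params, 120.0)
        nf = ps.synth_ppg(clean_params, beats, None, small_cohort,
                          rng=np.random.default_rng(3))
        fl = ps.synth_ppg(clean_params, beats, profile, small_cohort,
                          rng=np.random.default_rng(3))
        diff = fl.ir - nf.ir
        spec = ps.compute_spectrum(diff, nf.fs)
        peaks = ps.find_artifact_peaks(spec, fmin=1.0, n_peaks=2)
        got = sorted(f for f, _ in peaks)
        np.testing.assert_allclose(got, profile.freqs, atol=0.2)
        # everything away from the tones is numerically negligible
        off = (np.abs(spec.freqs[:, None] - np.array(profile.freqs)) > 1.0).all(axis=1)
        assert spec.power[off].max() < 1e-3 * spec.power.max()


class TestSynthAccel:
    def test_gravity_only_when_amplitudes_zero(self):
        profile = ps.VibrationProfile(accel_amplitudes=(0.0, 0.0))
        rec = ps.synth_accel(profile, 30.0, rng=np.random.default_rng(0))
        assert np.abs(rec.magnitude() - 1.0).max() < 0.1

    def test_fft_maxima_at_profile_frequencies(self):
        profile = ps.VibrationProfile()
        rec = ps.synth_accel(profile, 120.0, rng=np.random.default_rng(1))
        spec = ps.accel_spectrum(rec)
        peaks = ps.find_artifact_peaks(spec, fmin=10.0, n_peaks=2)
        np.testing.assert_allclose([f for f, _ in peaks], profile.freqs, atol=0.2)

    def test_head_vibration_below_seat(self):
        profile = ps.VibrationProfile()

        def band_rms(rec):
            mag = rec.magnitude() - rec.magnitude().mean()
            return np.std(bandpass(mag, rec.fs, (15.0, 40.0)))

        seat = ps.synth_accel(profile, 60.0, location="seat", rng=np.random.default_rng(2))
        head = ps.synth_accel(profile, 60.0, location="head", rng=np.random.default_rng(2))
        assert band_rms(head) < band_rms(seat)


class TestSynthReferenceVitals:
    def test_constant_rhythm_reads_60_bpm(self, subject_params):
        p = replace(subject_params, hr_mean=60.0, hr_sd_within=0.0)
        beats = ps.synth_beats(p, 120.0)
        ref = ps.synth_reference_vitals(p, beats, 120.0, hr_jitter_sd=0.0,
                                        spo2_noise_sd=0.0)
        valid = np.isfinite(ref.hr_ref)
        np.testing.assert_allclose(ref.hr_ref[valid], 60.0, atol=1e-9)

    def test_site_offset_shifts_reference(self, subject_params):
        p = replace(subject_params, spo2_true=96.8)
        beats = ps.synth_beats(p, 120.0)
        ref = ps.synth_reference_vitals(p, beats, 120.0, site_offset=-1.0,
                                        spo2_noise_sd=0.0)
        assert np.nanmean(ref.spo2_ref) == pytest.approx(95.8, abs=0.05)

    def test_one_hertz_grid(self, subject_params):
        beats = ps.synth_beats(subject_params, 90.0)
        ref = ps.synth_reference_vitals(subject_params, beats, 90.0)
        assert len(ref) == 90
        np.testing.assert_allclose(np.diff(ref.t), 1.0)


class TestGenerateCohort:
    def test_total_recorded_minutes(self):
        cohort = ps.CohortConfig()  # defaults: 16 subjects × 2 phases × 600 s
        minutes = cohort.n_subjects * 2 * cohort.phase_duration_s / 60.0
        assert minutes == 320.0

    def test_reproducible_csv_output(self, tmp_path, small_cohort):
        cohort = replace(small_cohort, n_subjects=2, phase_duration_s=60.0)
        ps.generate_cohort(cohort, out_dir=tmp_path / "a")
        ps.generate_cohort(cohort, out_dir=tmp_path / "b")
        for rel in ("S00/no_flight_ppg.csv", "S01/in_flight_ppg.csv",
                    "S00/in_flight_accel.csv", "S01/no_flight_ref.csv"):
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_no_flight_free_of_rotor_harmonics(self):
        # full-length records so the Welch floor estimate is well averaged
        cohort = ps.CohortConfig(n_subjects=2, phase_duration_s=600.0, master_seed=0)
        subjects = ps.generate_cohort(cohort)
        rec = subjects[0].ppg["no_flight"]
        spec = ps.compute_spectrum(rec.ir, rec.fs)
        floor = np.median(spec.power[(spec.freqs > 15) & (spec.freqs < 40)])
        for f_rotor in (23.5, 31.3):
            sel = np.abs(spec.freqs - f_rotor) < 0.3
            assert spec.power[sel].max() < 5.0 * floor
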
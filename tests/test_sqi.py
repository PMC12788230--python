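"""Quality-index formulas against hand computations and brute-force oracles."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ppgshake as ps
from ppgshake.exceptions import DataError
from ppgshake.filters import bandpass
from ppgshake.sqi import quality_indicator, validate_beats
from ppgshake.types import ChannelComponents


def _naive_skewness(x):
    mu = sum(x) / len(x)
    sigma = math.sqrt(sum((v - mu) ** 2 for v in x) / len(x))
    return sum(((v - mu) / sigma) ** 3 for v in x) / len(x)


def _naive_kurtosis(x):
    mu = sum(x) / len(x)
    sigma = math.sqrt(sum((v - mu) ** 2 for v in x) / len(x))
    return sum(((v - mu) / sigma) ** 4 for v in x) / len(x) - 3.0


def _naive_entropy(x):
    mu = sum(x) / len(x)
    c = [v - mu for v in x]
    e = sum(v * v for v in c)
    return -sum((v * v / e) * math.log(v * v / e) for v in c if v != 0.0)


class TestMoments:
    def test_symmetric_window_has_zero_skewness(self):
        t = np.linspace(0, 1, 1000, endpoint=False)
        assert ps.skewness(np.sin(2 * np.pi * 5 * t)) == pytest.approx(0.0, abs=1e-9)

    def test_skewness_hand_value(self):
        assert ps.skewness([0.0, 0.0, 0.0, 1.0]) == pytest.approx(2 / np.sqrt(3), abs=1e-12)

    def test_kurtosis_hand_value(self):
        assert ps.kurtosis([-1.0, -1.0, 1.0, 1.0]) == pytest.approx(-2.0, abs=1e-12)

    def test_sine_kurtosis_is_minus_three_halves(self):
        t = np.linspace(0, 1, 4000, endpoint=False)
        assert ps.kurtosis(np.sin(2 * np.pi * 4 * t)) == pytest.approx(-1.5, abs=1e-3)

    def test_gaussian_excess_kurtosis_near_zero(self):
        x = np.random.default_rng(0).standard_normal(200_000)
        assert ps.kurtosis(x) == pytest.approx(0.0, abs=0.1)

    def test_zero_variance_returns_missing(self):
        assert np.isnan(ps.skewness([2.0, 2.0, 2.0]))
        assert np.isnan(ps.kurtosis([2.0, 2.0, 2.0, 2.0]))

    @given(st.integers(0, 10**6))
    def test_oracle_equivalence_on_random_windows(self, seed):
        x = np.random.default_rng(seed).normal(size=64)
        assert ps.skewness(x) == pytest.approx(_naive_skewness(list(x)), abs=1e-12)
        assert ps.kurtosis(x) == pytest.approx(_naive_kurtosis(list(x)), abs=1e-12)
        assert ps.entropy(x) == pytest.approx(_naive_entropy(list(x)), abs=1e-10)

    def test_scipy_cross_check(self):
        from scipy import stats as spstats

        x = np.random.default_rng(5).normal(size=500)
        assert ps.skewness(x) == pytest.approx(spstats.skew(x, bias=True), abs=1e-12)
        assert ps.kurtosis(x) == pytest.approx(
            spstats.kurtosis(x, fisher=True, bias=True), abs=1e-12
        )


class TestEntropy:
    def test_single_nonzero_sample_gives_zero(self):
        assert ps.entropy([5.0]) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_energy_attains_log_n(self):
        n = 64
        x = np.array([1.0, -1.0] * (n // 2))  # zero-mean, equal |x|
        assert ps.entropy(x) == pytest.approx(np.log(n), abs=1e-12)

    def test_white_noise_bounded_by_log_n(self):
        x = np.random.default_rng(1).standard_normal(1000)
        h = ps.entropy(x)
        assert 0.0 < h <= np.log(1000)

    def test_all_zero_window_missing(self):
        assert np.isnan(ps.entropy(np.zeros(10)))


class TestScaleInvariance:
    @pytest.mark.parametrize("scale", [0.01, 3.0, 1e4])
    def test_moment_indices_invariant_under_positive_scaling(self, scale):
        x = np.random.default_rng(2).normal(size=256) + 0.3
        assert ps.skewness(scale * x) == pytest.approx(ps.skewness(x), abs=1e-9)
        assert ps.kurtosis(scale * x) == pytest.approx(ps.kurtosis(x), abs=1e-9)
        assert ps.entropy(scale * x) == pytest.approx(ps.entropy(x), abs=1e-9)

    def test_qi_invariant_under_scaling(self):
        fs = 200.0
        t = np.arange(int(6 * fs)) / fs
        x = np.sin(2 * np.pi * 1.2 * t) + 0.1 * np.random.default_rng(3).standard_normal(len(t))
        assert quality_indicator(5.0 * x, fs, 1.2) == pytest.approx(
            quality_indicator(x, fs, 1.2), abs=1e-9
        )


class TestPerfusionIndexAndOmega:
    def test_zero_ac_gives_zero_pi(self):
        assert ps.perfusion_index(np.zeros(100), np.full(100, 1.0)) == 0.0

    def test_constructed_two_percent(self):
        assert ps.perfusion_index(
            np.zeros(10), np.full(10, 1.0), beat_p2t=[0.02, 0.02, 0.02]
        ) == pytest.approx(2.0)

    def test_nonpositive_dc_rejected(self):
        with pytest.raises(DataError):
            ps.perfusion_index(np.zeros(10), np.full(10, -1.0))

    def test_identical_channels_give_unity_omega(self):
        comp = ChannelComponents(ac_r=0.01, dc_r=2.0, ac_ir=0.01, dc_ir=2.0)
        assert ps.omega(comp) == pytest.approx(1.0)

    def test_omega_arithmetic(self):
        comp = ChannelComponents(ac_r=0.0052, dc_r=1.0, ac_ir=0.0100, dc_ir=1.0)
        assert ps.omega(comp) == pytest.approx(0.52)

    def test_zero_ac_ir_missing(self):
        comp = ChannelComponents(ac_r=0.01, dc_r=1.0, ac_ir=0.0, dc_ir=1.0)
        assert np.isnan(ps.omega(comp))


class TestQualityIndicator:
    fs = 200.0

    def _train(self, f0=1.2, seconds=10.0):
        t = np.arange(int(seconds * self.fs)) / self.fs
        return np.exp(-0.5 * ((t * f0 % 1.0 - 0.5) / 0.13) ** 2), t

    def test_pure_pulse_train_dominates(self):
        train, _ = self._train()
        assert quality_indicator(train, self.fs, 1.2) >= 90.0

    def test_white_noise_scores_low(self):
        x = np.random.default_rng(0).standard_normal(int(10 * self.fs))
        assert quality_indicator(x, self.fs, 1.2) <= 20.0

    def test_equal_power_tone_halves_score(self):
        train, t = self._train()
        tone = np.sqrt(2 * np.var(train)) * np.sin(2 * np.pi * 23.5 * t)
        assert quality_indicator(train + tone, self.fs, 1.2) == pytest.approx(50.0, abs=10.0)

    def test_monotone_decrease_with_noise(self):
        train, _ = self._train()
        rng = np.random.default_rng(1)
        noise = rng.standard_normal(len(train))
        scores = [
            quality_indicator(train + sd * noise, self.fs, 1.2)
            for sd in (0.0, 0.05, 0.1, 0.2, 0.4)
        ]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_missing_pulse_rate_gives_missing(self):
        train, _ = self._train()
        assert np.isnan(quality_indicator(train, self.fs, float("nan")))


class TestValidPulseDetection:
    def _pulse_signal(self, fs=200.0, seconds=60.0, hr_hz=1.0):
        t = np.arange(int(seconds * fs)) / fs
        raw = np.exp(-0.5 * ((t * hr_hz % 1.0 - 0.5) / 0.10) ** 2)
        return bandpass(raw, fs, (0.5, 10.0)), t

    def test_clean_periodic_pulses_all_valid(self):
        fs = 200.0
        ac, _ = self._pulse_signal(fs)
        beats = ps.detect_beats(ac, fs)
        assert len(beats) > 40
        assert ps.valid_pulse_detection(ac, beats, fs) == pytest.approx(100.0, abs=3.0)

    def test_flat_signal_reports_zero(self):
        fs = 200.0
        assert ps.valid_pulse_detection(
            np.zeros(1000), ps.BeatSeries(peak_times=np.array([])), fs
        ) == 0.0

    def test_corrupting_every_fourth_beat(self):
        # every 4th beat waveform replaced by a narrow artifact transient:
        # it is still detected as a beat but fails the morphology check
        fs = 200.0
        t = np.arange(int(120 * fs)) / fs
        raw = np.exp(-0.5 * ((t % 1.0 - 0.5) / 0.10) ** 2)
        for k in range(2, 118, 4):
            sel = (t >= k) & (t < k + 1)
            raw[sel] = 1.3 * np.exp(-0.5 * ((t[sel] - k - 0.5) / 0.03) ** 2)
        ac = bandpass(raw, fs, (0.5, 10.0))
        beats = ps.detect_beats(ac, fs)
        vpd = ps.valid_pulse_detection(ac, beats, fs)
        assert vpd == pytest.approx(75.0, abs=5.0)


class TestDecomposeAcDc:
    def test_constant_signal(self):
        rec = ps.PPGRecord(red=np.full(4000, 2.0), ir=np.full(4000, 3.0))
        ac_ir, dc_ir, ac_r, dc_r = ps.decompose_ac_dc(rec)
        assert np.abs(ac_ir).max() < 1e-9 and np.abs(dc_ir - 3.0).max() < 1e-9
        assert np.abs(ac_r).max() < 1e-9 and np.abs(dc_r - 2.0).max() < 1e-9

    def test_in_band_sinusoid_passes_to_ac(self):
        fs = 200.0
        t = np.arange(int(30 * fs)) / fs
        x = 2.0 + 0.1 * np.sin(2 * np.pi * 1.2 * t)
        rec = ps.PPGRecord(red=x, ir=x, fs=fs)
        ac_ir, dc_ir, *_ = ps.decompose_ac_dc(rec)
        mid = slice(int(5 * fs), int(25 * fs))
        np.testing.assert_allclose(dc_ir[mid], 2.0, atol=0.005)
        np.testing.assert_allclose(ac_ir[mid], 0.1 * np.sin(2 * np.pi * 1.2 * t)[mid], atol=0.01)

    def test_rotor_tone_rejected_from_both_components(self):
        fs = 200.0
        t = np.arange(int(30 * fs)) / fs
        tone = 0.1 * np.sin(2 * np.pi * 23.5 * t)
        rec = ps.PPGRecord(red=2.0 + tone, ir=2.0 + tone, fs=fs)
        ac_ir, dc_ir, *_ = ps.decompose_ac_dc(rec)
        mid = slice(int(5 * fs), int(25 * fs))
        # ≥ 20 dB attenuation of the 23.5 Hz tone in the AC path
        assert np.std(ac_ir[mid]) < 0.1 * np.std(tone)
        assert np.std(dc_ir[mid] - 2.0) < 0.01 * np.std(tone)

    def test_too_short_record_rejected(self):
        rec = ps.PPGRecord(red=np.ones(100), ir=np.ones(100))
        with pytest.raises(DataError):
            ps.decompose_ac_dc(rec)


class TestExtractSqiSeries:
    def test_600s_record_yields_120_windows(self, clean_params):
        cohort = ps.CohortConfig(n_subjects=2, phase_duration_s=600.0)
        beats = ps.synth_beats(clean_params, 600.0)
        rec = ps.synth_ppg(clean_params, beats, None, cohort)
        series = ps.extract_sqi_series(rec)
        assert len(series) == 120

    def test_deterministic(self, clean_record):
        rec, _ = clean_record
        a = ps.extract_sqi_series(rec)
        b = ps.extract_sqi_series(rec)
        for name in a.values:
            np.testing.assert_array_equal(a[name], b[name])

    def test_record_too_short_rejected(self):
        rec = ps.PPGRecord(red=np.ones(2000), ir=np.ones(2000))
        with pytest.raises(DataError):
            ps.extract_sqi_series(rec)
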
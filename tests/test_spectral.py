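"""Spectral core: FFT, dominant-bin cadence, correction, peaks baseline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import facecadence as fc
from facecadence.spectral import DegenerateSignalError, _ols

from conftest import naive_dft

FS = 30.0
N = 128
BIN_SPM = FS / N * 60.0  # one frequency bin in steps/min


def make_window(samples, fs=FS):
    return fc.Window(samples=np.asarray(samples, float), sample_rate=fs)


def cosine_window(bin_k: int, amplitude: float = 1.0, n: int = N, phase: float = 0.0):
    t = np.arange(n)
    return amplitude * np.cos(2 * np.pi * bin_k * t / n + phase)


class TestFFT:
    def test_impulse(self):
        assert np.allclose(fc.fft_radix2([1, 0, 0, 0]), [1, 1, 1, 1])

    def test_constant_is_dc_only(self):
        assert np.allclose(fc.fft_radix2([1, 1, 1, 1]), [4, 0, 0, 0])

    @pytest.mark.parametrize("n", [2, 4, 8, 16, 32, 64, 128, 256])
    def test_matches_naive_dft_oracle(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n) + 1j * rng.normal(size=n)
        got = fc.fft_radix2(x)
        ref = naive_dft(x)
        assert np.max(np.abs(got - ref)) / np.max(np.abs(ref)) < 1e-9

    @pytest.mark.parametrize("n", [3, 5, 12, 100])
    def test_rejects_non_power_of_two(self, n):
        with pytest.raises(ValueError):
            fc.fft_radix2(np.ones(n))

    def test_parseval_energy_conservation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=64)
        spec = fc.fft_radix2(x)
        assert np.isclose(np.sum(np.abs(spec) ** 2) / 64, np.sum(x**2), rtol=1e-12)

    def test_inverse_reconstructs(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=32)
        spec = fc.fft_radix2(x)
        # inverse via conjugate trick
        back = np.conj(fc.fft_radix2(np.conj(spec))) / 32
        assert np.allclose(back.real, x, atol=1e-12)


class TestRawEstimate:
    def test_bin_center_cosine(self):
        est = fc.estimate_cadence_raw(make_window(cosine_window(10)))
        assert est.dominant_bin == 10
        assert est.raw_spm == pytest.approx(140.625, abs=1e-12)

    def test_printed_bin_to_spm_mapping(self):
        est = fc.estimate_cadence_raw(make_window(cosine_window(7)))
        assert est.dominant_frequency == pytest.approx(7 / (128 / 30))
        assert est.raw_spm == pytest.approx(98.4375)

    def test_discard_rule_excludes_low_bins(self):
        sig = cosine_window(3, amplitude=10.0) + cosine_window(12, amplitude=1.0)
        est = fc.estimate_cadence_raw(make_window(sig))
        assert est.dominant_bin == 12
        assert est.raw_spm == pytest.approx(168.75)

    def test_constant_signal_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            fc.estimate_cadence_raw(make_window(np.full(N, 3.7)))

    def test_tie_breaks_to_lowest_bin(self):
        # unit impulse: every bin has magnitude exactly 1 -> all tied;
        # the lowest searched bin (5) must win
        sig = np.zeros(N)
        sig[0] = 1.0
        est = fc.estimate_cadence_raw(make_window(sig))
        assert est.dominant_bin == 5
        assert est.raw_spm == pytest.approx(5 * BIN_SPM)

    @given(offset=st.floats(-1e4, 1e4, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_offset_invariance(self, offset):
        base = cosine_window(9)
        a = fc.estimate_cadence_raw(make_window(base))
        b = fc.estimate_cadence_raw(make_window(base + offset))
        assert a.dominant_bin == b.dominant_bin
        assert a.raw_spm == b.raw_spm

    def test_monotone_in_dominant_bin(self):
        spms = [
            fc.estimate_cadence_raw(make_window(cosine_window(k))).raw_spm
            for k in range(5, 30)
        ]
        assert np.all(np.diff(spms) > 0)

    @pytest.mark.parametrize("f_hz", np.linspace(1.5, 3.0, 16))
    def test_half_bin_quantization_bound(self, f_hz):
        t = np.arange(N) / FS
        est = fc.estimate_cadence_raw(make_window(np.cos(2 * np.pi * f_hz * t)))
        assert abs(est.raw_spm - 60 * f_hz) <= 0.5 * BIN_SPM + 1e-9


class TestCorrection:
    def test_printed_model_evaluation(self, stated_model):
        assert fc.apply_correction(150.0, stated_model) == pytest.approx(138.2)

    def test_identity_model(self):
        ident = fc.CorrectionModel(slope=1.0, intercept=0.0)
        assert fc.apply_correction(123.4, ident) == 123.4

    def test_apply_invert_round_trip(self, stated_model):
        y = fc.apply_correction(147.3, stated_model)
        assert stated_model.invert(y) == pytest.approx(147.3, abs=1e-12)

    def test_exact_line_recovered(self):
        raw = np.linspace(120, 200, 20)
        truth = 0.83 * raw + 13.70
        m = fc.fit_correction(raw, truth)
        assert m.slope == pytest.approx(0.83, abs=1e-12)
        assert m.intercept == pytest.approx(13.70, abs=1e-10)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_simple_shifted_line(self):
        m = fc.fit_correction([0, 1, 2], [1, 2, 3], k_folds=0)
        assert m.slope == pytest.approx(1.0)
        assert m.intercept == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(100, 200, 40)
        y = 0.9 * x + 5 + rng.normal(0, 3, 40)
        m = fc.fit_correction(x, y, seed=1)
        # oracle: solve the normal equations of the 2-column design directly
        A = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert m.slope == pytest.approx(beta[0], abs=1e-9)
        assert m.intercept == pytest.approx(beta[1], abs=1e-9)

    def test_recovery_within_3se_under_noise(self):
        """OLS re-finds the generating line within 3 SE in ~all replicates."""
        rng = np.random.default_rng(42)
        hits_a = hits_b = 0
        reps = 100
        for _ in range(reps):
            x = rng.uniform(120, 200, 30)
            y = 0.83 * x + 13.70 + rng.normal(0, 4.0, 30)
            m = fc.fit_correction(x, y, k_folds=0)
            sxx = np.sum((x - x.mean()) ** 2)
            se_a = m.residual_se / np.sqrt(sxx)
            se_b = m.residual_se * np.sqrt(1 / 30 + x.mean() ** 2 / sxx)
            hits_a += abs(m.slope - 0.83) <= 3 * se_a
            hits_b += abs(m.intercept - 13.70) <= 3 * se_b
        assert hits_a >= 96 and hits_b >= 96

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            fc.fit_correction([150, 150, 150], [140, 141, 142], k_folds=0)

    def test_cv_mae_reported_and_reasonable(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(120, 200, 33)
        y = 0.83 * x + 13.70 + rng.normal(0, 5, 33)
        m = fc.fit_correction(x, y, k_folds=5, seed=3)
        assert m.cv_mae is not None and 0 < m.cv_mae < 15


class TestPeaksBaseline:
    def test_clean_cosine_count_quantization(self):
        t = np.arange(N) / FS
        spm = fc.estimate_cadence_peaks(make_window(np.cos(2 * np.pi * 2.5 * t)))
        # 2.5 Hz over 4.2667 s holds ~10.7 cycles; interior maxima number 10 or 11
        assert spm in (pytest.approx(140.625), pytest.approx(154.6875))

    def test_monotone_ramp_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            fc.estimate_cadence_peaks(make_window(np.linspace(0, 1, N)))

    @pytest.mark.parametrize("frac", [0.1, 0.5, 1.0])
    def test_prominence_inactive_on_clean_signal(self, frac):
        t = np.arange(N) / FS
        w = make_window(np.cos(2 * np.pi * 2.5 * t))
        assert fc.estimate_cadence_peaks(w, min_prominence_frac=frac) == (
            fc.estimate_cadence_peaks(w, min_prominence_frac=0.5)
        )


class TestWindowExtraction:
    def test_stated_policy_arithmetic(self):
        trace = fc.LandmarkTrace(sample_rate=30.0, nose_y=np.sin(np.arange(1800) / 3))
        w = fc.extract_analysis_window(trace, skip=10.0, length=128)
        assert w.origin[1] == 300 + (1500 - 128) // 2 == 986
        assert len(w) == 128

    def test_exact_fit_no_slack(self):
        trace = fc.LandmarkTrace(sample_rate=30.0, nose_y=np.sin(np.arange(428) / 3))
        w = fc.extract_analysis_window(trace)
        assert w.origin[1] == 300

    def test_too_short_raises(self):
        trace = fc.LandmarkTrace(sample_rate=30.0, nose_y=np.zeros(200))
        with pytest.raises(ValueError):
            fc.extract_analysis_window(trace)

    def test_window_duration_constant(self):
        w = make_window(cosine_window(10))
        assert w.duration == pytest.approx(128 / 30)
        assert round(w.duration, 2) == 4.27


class TestStreaming:
    def test_stationary_trace_constant_estimates(self, stated_model):
        # bin 100 of 1280 samples == bin 10 of every 128-sample window
        trace = fc.LandmarkTrace(
            sample_rate=30.0, nose_y=cosine_window(100, n=1280), trace_id="stat"
        )
        ests = fc.stream_estimates(trace, stated_model, hop=128)
        assert len(ests) == 10
        assert all(e.raw_spm == pytest.approx(140.625) for e in ests)
        assert all(
            e.corrected_spm == pytest.approx(0.83 * 140.625 + 13.70) for e in ests
        )

    def test_hop_64_count(self, stated_model):
        trace = fc.LandmarkTrace(sample_rate=30.0, nose_y=cosine_window(100, n=1280))
        assert len(fc.stream_estimates(trace, stated_model, hop=64)) == 19

    def test_step_change_transition(self, stated_model):
        # per-128-window bin-center segments: bin 10 (140.625 spm) then
        # bin 12 (168.75 spm); bins 50/60 of the 640-sample segments
        t1 = cosine_window(50, n=640)
        t2 = cosine_window(60, n=640)
        trace = fc.LandmarkTrace(sample_rate=30.0, nose_y=np.concatenate([t1, t2]))
        ests = fc.stream_estimates(trace, stated_model, hop=128)
        raw = [e.raw_spm for e in ests]
        assert raw[:5] == [pytest.approx(140.625)] * 5
        assert raw[5:] == [pytest.approx(168.75)] * 5

    def test_degenerate_windows_skipped(self, stated_model):
        nose = np.concatenate([np.zeros(128), cosine_window(10)])
        trace = fc.LandmarkTrace(sample_rate=30.0, nose_y=nose)
        ests = fc.stream_estimates(trace, stated_model, hop=128)
        assert len(ests) == 1 and ests[0].origin[1] == 128


def test_ols_helper_centering():
    x = np.array([10.0, 20.0, 30.0])
    slope, intercept = _ols(x, 2 * x - 7)
    assert slope == pytest.approx(2.0) and intercept == pytest.approx(-7.0)
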
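import numpy as np
import pytest

from vtwarn.features import (
    DegenerateSignalError,
    SpectralGrid,
    build_spectral_grid,
    dfa_exponents,
    extract_feature_row,
    hjorth_parameters,
    log_band_powers,
    lomb_periodogram,
    mean_nn_interval,
)
from vtwarn.records import RRValidationError
from vtwarn.synth import _spectral_series


class TestMeanNN:
    def test_constant_window(self):
        assert mean_nn_interval(np.full(100, 0.8)) == pytest.approx(0.8)

    def test_arithmetic_mean(self):
        assert mean_nn_interval([0.7, 0.8, 0.9]) == pytest.approx(0.8)

    def test_empty_window_rejected(self):
        with pytest.raises(RRValidationError):
            mean_nn_interval([])


class TestHjorth:
    def test_alternating_sequence_limits(self):
        # y = +-1: var(y)=1, var(dy)=4, var(d2y)=16 in the long-sequence limit
        y = np.tile([1.0, -1.0], 5000)
        activity, mobility, complexity = hjorth_parameters(y)
        assert activity == pytest.approx(1.0, rel=1e-6)
        assert mobility == pytest.approx(2.0, rel=1e-3)
        assert complexity == pytest.approx(1.0, rel=1e-3)

    def test_slow_sinusoid(self):
        # mobility of sin(w i) -> 2 sin(w/2); a pure tone has unit complexity
        w = 0.01
        y = np.sin(w * np.arange(100_000))
        _, mobility, complexity = hjorth_parameters(y)
        assert mobility == pytest.approx(2 * np.sin(w / 2), rel=1e-3)
        assert complexity == pytest.approx(1.0, rel=1e-3)

    def test_matches_bruteforce_variance_ratios(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(512)
        activity, mobility, complexity = hjorth_parameters(y)
        v0, v1, v2 = y.var(), np.diff(y).var(), np.diff(y, 2).var()
        assert activity == pytest.approx(v0)
        assert mobility == pytest.approx(np.sqrt(v1 / v0))
        assert complexity == pytest.approx(np.sqrt(v2 / v1) / np.sqrt(v1 / v0))

    def test_constant_window_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            hjorth_parameters(np.full(10, 0.8))

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        y = 0.8 + 0.05 * rng.standard_normal(1000)
        _, mob, cplx = hjorth_parameters(y)
        act_s, mob_s, cplx_s = hjorth_parameters(3.0 * y)
        assert mob_s == pytest.approx(mob)
        assert cplx_s == pytest.approx(cplx)
        assert act_s == pytest.approx(9.0 * hjorth_parameters(y)[0])


class TestDFA:
    def _median_alphas(self, make_series, n_rep=50, n=1000):
        rng = np.random.default_rng(11)
        pairs = [dfa_exponents(make_series(rng, n)) for _ in range(n_rep)]
        return np.median(pairs, axis=0)

    def test_white_noise_recovers_half(self):
        a1, a2 = self._median_alphas(lambda rng, n: rng.standard_normal(n))
        assert a1 == pytest.approx(0.5, abs=0.1)
        assert a2 == pytest.approx(0.5, abs=0.1)

    def test_brownian_noise_recovers_three_halves(self):
        a1, a2 = self._median_alphas(
            lambda rng, n: np.cumsum(rng.standard_normal(n))
        )
        assert a1 == pytest.approx(1.5, abs=0.15)
        assert a2 == pytest.approx(1.5, abs=0.15)

    def test_pink_noise_recovers_one(self):
        a1, a2 = self._median_alphas(
            lambda rng, n: _spectral_series(n, rng, gamma=1.0, f_knee=0.5, knee_exponent=6.0)
        )
        assert a1 == pytest.approx(1.0, abs=0.15)
        assert a2 == pytest.approx(1.0, abs=0.15)

    def test_short_window_rejected(self):
        with pytest.raises(RRValidationError):
            dfa_exponents(np.random.default_rng(0).standard_normal(100))

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(800)
        np.testing.assert_allclose(dfa_exponents(y), dfa_exponents(5.0 * y), rtol=1e-9)


class TestLomb:
    def test_matches_dft_periodogram_on_even_grid(self):
        rng = np.random.default_rng(9)
        n, dt = 256, 1.2
        t = dt * np.arange(1, n + 1)
        y = rng.standard_normal(n)
        # exact Fourier frequencies k/(n dt), below Nyquist
        k = np.arange(1, n // 2 - 1)
        freqs = k / (n * dt)
        grid = SpectralGrid(
            frequencies=freqs,
            bin_edges=np.logspace(np.log10(freqs[0]), np.log10(0.5), 6),
        )
        density = lomb_periodogram(t, y, grid)
        yc = y - y.mean()
        dft = np.abs(np.fft.rfft(yc)[k]) ** 2 / n  # periodogram |Y_k|^2 / n
        np.testing.assert_allclose(density, 2.0 * dt * dft, rtol=1e-6, atol=1e-9)

    def test_sinusoid_peak_at_true_frequency(self):
        t = np.cumsum(np.full(512, 0.8))
        y = 0.05 * np.sin(2 * np.pi * 0.1 * t)
        grid = build_spectral_grid(float(t[-1]))
        density = lomb_periodogram(t, y, grid)
        assert grid.frequencies[np.argmax(density)] == pytest.approx(0.1, abs=2 * grid.df)

    def test_constant_signal_all_zero(self):
        t = np.cumsum(np.full(64, 0.8))
        grid = build_spectral_grid(float(t[-1]))
        assert np.all(lomb_periodogram(t, np.full(64, 0.8), grid) == 0.0)

    def test_duplicate_times_rejected(self):
        t = np.cumsum(np.full(64, 0.8))
        t[10] = t[9]
        grid = build_spectral_grid(50.0)
        with pytest.raises(RRValidationError):
            lomb_periodogram(t, np.ones(64), grid)


class TestBandPowers:
    def test_band_powers_sum_to_total_grid_power(self):
        rng = np.random.default_rng(2)
        window = 0.8 + 0.05 * rng.standard_normal(1000)
        powers, grid = log_band_powers(window)
        density = lomb_periodogram(np.cumsum(window), window, grid)
        assert powers.sum() == pytest.approx(float((density * grid.df).sum()), rel=1e-12)
        assert (powers >= 0).all()

    def test_high_frequency_tone_lands_in_top_bin(self):
        i = np.arange(1000)
        window = 0.8 + 0.02 * np.sin(2 * np.pi * 0.4 * 0.8 * i)  # ~0.4 Hz tone
        powers, _ = log_band_powers(window)
        assert powers[4] / powers.sum() > 0.95

    def test_grid_edges_log_equispaced_to_half_hz(self):
        _, grid = log_band_powers(0.8 + 0.01 * np.random.default_rng(0).standard_normal(600))
        ratios = np.diff(np.log10(grid.bin_edges))
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)
        assert grid.bin_edges[-1] == pytest.approx(0.5)
        assert grid.bin_edges[0] == pytest.approx(1.0 / np.sum(
            0.8 + 0.01 * np.random.default_rng(0).standard_normal(600)), rel=1e-9)


class TestFeatureRow:
    def test_deterministic_and_complete(self):
        rng = np.random.default_rng(1)
        window = 0.8 + 0.05 * rng.standard_normal(1000)
        meta = {"patient_id": "p", "record_id": "r", "label": "regular"}
        row1 = extract_feature_row(window, meta)
        row2 = extract_feature_row(window.copy(), meta)
        assert row1 == row2
        d = row1.as_dict()
        scalar_keys = {
            "mean_nn", "hjorth_mobility", "hjorth_complexity", "alpha1", "alpha2",
            "bp1", "bp2", "bp3", "bp4", "bp5",
        }
        assert scalar_keys <= set(d)
        assert len(scalar_keys) == 10 and row1.pc_coeffs == ()
        assert d["mean_nn"] > 0 and all(d[f"bp{i}"] >= 0 for i in range(1, 6))

    def test_errors_carry_record_context(self):
        with pytest.raises(RRValidationError, match="record r7"):
            extract_feature_row(np.full(1000, 0.8), {"record_id": "r7"})
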
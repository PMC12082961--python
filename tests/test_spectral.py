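"""Maximum-entropy spectral estimation: Burg fit consistency, PSD closed
forms, band power behaviour, and cross-checks against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import veinmod as vm
from veinmod import spectral, synthetic
from veinmod.errors import (ConfigError, DegenerateSeriesError,
                            UnsupportedConditionError)
from veinmod.spectral import ARModel, BAND_PB10, BAND_PB3, BandSpec


def _ar1(phi, n, seed=0, sigma=1.0):
    rng = np.random.default_rng(seed)
    e = rng.normal(0, sigma, n)
    x = np.zeros(n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    return x


class TestFitBurg:
    def test_ar1_long_sample_consistency(self):
        """a_1 -> -phi for x_t = 0.6 x_{t-1} + e_t (denominator convention)."""
        m = spectral.fit_burg(_ar1(0.6, 5000), order=1)
        assert m.coefficients[0] == pytest.approx(-0.6, abs=0.05)

    def test_matches_statsmodels_burg(self):
        """Independent implementation agrees (their rho_k = -a_k)."""
        from statsmodels.regression.linear_model import burg as sm_burg
        x = _ar1(0.5, 400, seed=3)
        m = spectral.fit_burg(x, order=4)
        rho, _ = sm_burg(x, order=4, demean=True)
        np.testing.assert_allclose(m.coefficients, -rho, atol=1e-8)

    def test_white_noise_small_reflections(self):
        ks, ratios = [], []
        for seed in range(200):
            x = np.random.default_rng(seed).normal(0, 1, 200)
            m = spectral.fit_burg(x, order=7)
            ks.append(np.max(np.abs(m.reflection)))
            ratios.append(m.noise_variance / x.var())
        assert np.mean(ks) < 0.15
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)

    def test_stability_of_reflections(self, pb10_pattern):
        s = synthetic.make_diameter_series(
            pb10_pattern, synthetic.GroundTruth(d0=2.4, amp=0.05,
                                                noise_sd_diameter=0.02), seed=1)
        m = spectral.fit_burg(s, order=7)
        assert np.all(np.abs(m.reflection) < 1.0)

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            spectral.fit_burg(np.full(50, 2.4), order=7)

    def test_short_series_rejected(self):
        with pytest.raises(ConfigError):
            spectral.fit_burg(np.arange(5.0), order=7)


class TestMemPsd:
    def test_order0_flat_closed_form(self):
        m = ARModel(order=0, coefficients=np.array([]), noise_variance=2.0)
        spec = spectral.mem_psd(m)
        np.testing.assert_allclose(spec.psd, 2 * 2.0 * 1.0)
        assert spec.total_power() == pytest.approx(2.0, rel=1e-6)

    def test_ar1_shape_against_closed_form(self):
        """P(f) proportional to 1/|1 - 0.6 e^{-i2 pi f}|^2, max at f=0."""
        m = ARModel(order=1, coefficients=np.array([-0.6]), noise_variance=1.0)
        spec = spectral.mem_psd(m)
        f = spec.freqs_hz
        closed = 2.0 / np.abs(1 - 0.6 * np.exp(-2j * np.pi * f)) ** 2
        np.testing.assert_allclose(spec.psd, closed, rtol=1e-10)
        assert np.argmax(spec.psd) == 0
        assert np.all(np.diff(spec.psd) <= 1e-12)

    def test_sinusoid_peak_location_vs_periodogram(self):
        t = np.arange(50.0)
        x = 0.05 * np.cos(2 * np.pi * 0.1 * t)
        spec = spectral.mem_psd(spectral.fit_burg(x, order=7))
        f_peak = spec.freqs_hz[np.argmax(spec.psd)]
        assert 0.095 <= f_peak <= 0.105
        # periodogram oracle peaks at the same frequency bin
        xd = x - x.mean()
        pgram = np.abs(np.fft.rfft(xd)) ** 2
        f_pg = np.fft.rfftfreq(50, d=1.0)[np.argmax(pgram)]
        assert abs(f_peak - f_pg) < 0.01

    def test_parseval_normalization(self):
        """PSD integral ~ detrended variance for AR-generated series."""
        for seed in range(10):
            x = _ar1(0.5, 50, seed=seed)
            spec = spectral.mem_psd(spectral.fit_burg(x, order=7))
            var = (x - x.mean()).var()
            assert spec.total_power() == pytest.approx(var, rel=0.10)

    def test_grid_outside_nyquist_rejected(self):
        m = ARModel(order=0, coefficients=np.array([]), noise_variance=1.0)
        with pytest.raises(ConfigError):
            spectral.mem_psd(m, np.array([0.0, 0.7]))


class TestBandLogPower:
    def test_flat_psd_closed_form(self):
        spec = spectral.Spectrum(np.linspace(0, 0.5, 5001),
                                 np.full(5001, 3.0))
        lp = spectral.band_logpower(spec, BAND_PB10)
        assert lp.value == pytest.approx(np.log(3.0 * 0.002), rel=1e-6)

    def test_amplitude_doubling_adds_2ln2(self):
        t = np.arange(50.0)
        x = 0.05 * np.cos(2 * np.pi * 0.1 * t) + \
            np.random.default_rng(0).normal(0, 0.005, 50)
        lp1 = spectral.band_logpower(
            spectral.mem_psd(spectral.fit_burg(x, 7)), BAND_PB10)
        lp2 = spectral.band_logpower(
            spectral.mem_psd(spectral.fit_burg(2 * x, 7)), BAND_PB10)
        assert lp2.value - lp1.value == pytest.approx(2 * np.log(2), abs=1e-6)

    def test_band_selectivity(self):
        """A 0.333 Hz tone leaves almost no power in the 0.1 Hz band."""
        t = np.arange(50.0)
        x = 0.05 * np.cos(2 * np.pi * (1 / 3) * t) + \
            np.random.default_rng(1).normal(0, 0.002, 50)
        spec = spectral.mem_psd(spectral.fit_burg(x, 7))
        p10 = np.exp(spectral.band_logpower(spec, BAND_PB10).value)
        p3 = np.exp(spectral.band_logpower(spec, BAND_PB3).value)
        assert p10 / p3 < 0.01

    def test_coarse_grid_rejected(self):
        spec = spectral.Spectrum(np.linspace(0, 0.5, 100), np.ones(100))
        with pytest.raises(ConfigError):
            spectral.band_logpower(spec, BAND_PB10)

    def test_zero_power_degenerate_sentinel(self):
        freqs = np.linspace(0, 0.5, 5001)
        spec = spectral.Spectrum(freqs, np.zeros(5001))
        lp = spectral.band_logpower(spec, BAND_PB10)
        assert lp.degenerate and lp.value == -np.inf


class TestModulationMagnitude:
    def test_end_to_end_amplitude_ratio(self, pb10_pattern):
        a = synthetic.make_diameter_series(
            pb10_pattern, synthetic.GroundTruth(d0=2.4, amp=0.05), seed=0)
        b = synthetic.make_diameter_series(
            pb10_pattern, synthetic.GroundTruth(d0=2.4, amp=0.025), seed=0)
        la = spectral.modulation_magnitude(a, "PB10").value
        lb = spectral.modulation_magnitude(b, "PB10").value
        assert la - lb == pytest.approx(2 * np.log(2), abs=0.1)

    def test_sb_unsupported(self, pb10_pattern):
        s = synthetic.make_diameter_series(
            pb10_pattern, synthetic.GroundTruth(d0=2.4, amp=0.05))
        with pytest.raises(UnsupportedConditionError):
            spectral.modulation_magnitude(s, "SB")

    def test_cohort_direction_pb10_exceeds_pb3(self):
        """Larger amplitude at the slower paced frequency -> larger log power."""
        cohort = synthetic.make_cohort(n_participants=6, seed=4,
                                       conditions=["PB3", "PB10"],
                                       include_respiration=False)
        by_cond = {"PB3": [], "PB10": []}
        for r in cohort.recordings:
            by_cond[r.condition.value].append(
                spectral.modulation_magnitude(r.series, r.condition).value)
        assert np.mean(by_cond["PB10"]) > np.mean(by_cond["PB3"])

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.floats(0.25, 4.0), st.integers(0, 50))
    def test_scale_equivariance_property(self, k, seed):
        """Multiplying a series by k shifts log band power by exactly 2 ln k."""
        rng = np.random.default_rng(seed)
        t = np.arange(50.0)
        x = 0.05 * np.cos(2 * np.pi * 0.1 * t) + rng.normal(0, 0.01, 50)
        base = spectral.band_logpower(
            spectral.mem_psd(spectral.fit_burg(x, 7)), BAND_PB10).value
        scaled = spectral.band_logpower(
            spectral.mem_psd(spectral.fit_burg(k * x, 7)), BAND_PB10).value
        assert scaled - base == pytest.approx(2 * np.log(k), abs=1e-6)
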
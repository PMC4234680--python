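"""SpO2 feature operations: statistics, desaturation indices, regularity
measures (against brute-force oracles), and AR-spectral features."""

import numpy as np
import pytest
from scipy.signal import lfilter

import oracles
from oxiscreen import ar
from oxiscreen.config import PipelineConfig
from oxiscreen.spo2 import (
    approximate_entropy,
    central_tendency_measure,
    count_desaturations,
    delta_index,
    fit_ar_psd,
    interpolate_gaps,
    modulation_band_features,
    sample_entropy,
    spo2_basic_stats,
    spo2_window_features,
    time_below,
)


class TestBasicStats:
    def test_constant(self):
        assert spo2_basic_stats(np.full(4, 96.0)) == (96.0, 96.0, 0.0, 0.0)

    def test_arithmetic(self):
        mean, median, _, _ = spo2_basic_stats(np.array([94.0, 95.0, 96.0, 97.0]))
        assert mean == 95.5 and median == 95.5

    def test_nan_excluded(self):
        mean, *_ = spo2_basic_stats(np.array([94.0, np.nan, 96.0]))
        assert mean == 95.0

    def test_sampling_distribution_of_std(self, rng):
        """SD of 120 Gaussian draws concentrates near the truth."""
        stds = [spo2_basic_stats(rng.normal(96, 0.5, 120))[2] for _ in range(50)]
        assert all(0.35 < s < 0.65 for s in stds)


class TestDeltaIndex:
    def test_constant_is_zero(self):
        assert delta_index(np.full(120, 96.0)) == 0.0

    def test_block_means_arithmetic(self):
        x = np.concatenate([np.full(12, 96.0), np.full(12, 94.0), np.full(12, 96.0)])
        assert delta_index(x) == pytest.approx(2.0)

    def test_square_wave(self):
        """98/94 alternating every 12 s: block means differ by 4."""
        x = np.tile(np.concatenate([np.full(12, 98.0), np.full(12, 94.0)]), 5)
        assert delta_index(x) == pytest.approx(4.0)

    def test_matches_bruteforce_on_random_traces(self, rng):
        for _ in range(20):
            x = rng.normal(96, 1, 120)
            x[rng.random(120) < 0.1] = np.nan
            assert delta_index(x) == pytest.approx(
                oracles.delta_index_bruteforce(list(x), 12), abs=1e-12
            )


class TestDesaturations:
    def test_constant_no_events(self):
        assert count_desaturations(np.full(120, 96.0)) == 0

    def test_two_planted_dips_counted(self):
        x = np.full(120, 96.0)
        x[30:40] = 93.0
        x[80:90] = 93.0
        assert count_desaturations(x) == 2

    def test_shallow_dip_ignored(self):
        x = np.full(120, 96.0)
        x[30:40] = 95.0  # depth 1 < 2
        assert count_desaturations(x) == 0

    def test_brief_dip_ignored(self):
        x = np.full(120, 96.0)
        x[30:32] = 92.0  # 2 s < 3 s minimum
        assert count_desaturations(x) == 0


class TestTimeBelow:
    def test_none_below(self):
        assert time_below(np.full(120, 95.0)) == 0.0

    def test_counts_seconds(self):
        x = np.full(120, 95.0)
        x[10:17] = 90.0
        assert time_below(x) == 7.0

    def test_threshold_94(self):
        x = np.full(120, 95.0)
        x[50:70] = 93.0
        assert time_below(x, sat_threshold=94.0) == 20.0


class TestRegularity:
    def test_apen_constant_zero(self):
        assert approximate_entropy(np.full(50, 96.0)) == 0.0

    def test_sampen_constant_zero(self):
        assert sample_entropy(np.full(50, 96.0)) == 0.0

    def test_alternating_series_matches_oracle(self):
        x = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2], float)
        r = 0.5 * x.std()
        assert approximate_entropy(x, 1, r) == pytest.approx(
            oracles.apen_bruteforce(x, 1, r), abs=1e-12
        )

    def test_entropy_oracle_equivalence_random(self, rng):
        """ApEn and SampEn equal O(n^2) brute force on random series."""
        for _ in range(15):
            n = rng.integers(20, 120)
            x = rng.normal(96, 1, n).round(1)
            m = int(rng.integers(1, 3))
            r = 0.25 * x.std() + 1e-6
            assert approximate_entropy(x, m, r) == pytest.approx(
                oracles.apen_bruteforce(x, m, r), abs=1e-12
            )
            se = sample_entropy(x, m, r)
            se_ref = oracles.sampen_bruteforce(x, m, r)
            if np.isnan(se_ref):
                assert np.isnan(se)
            else:
                assert se == pytest.approx(se_ref, abs=1e-12)

    def test_noise_more_irregular_than_sinusoid(self, rng):
        t = np.arange(120.0)
        sine = 96 + np.sin(2 * np.pi * 0.05 * t)
        noise = 96 + rng.standard_normal(120)
        for fn in (approximate_entropy, sample_entropy):
            assert fn(noise, 1, 0.25) > fn(sine, 1, 0.25)

    def test_ctm_degenerate_cases(self):
        assert central_tendency_measure(np.full(50, 96.0)) == 1.0
        big = 96 + 5 * np.resize([1.0, -1.0], 50)
        assert central_tendency_measure(big, rho=0.25) == 0.0

    def test_ctm_oracle_equivalence(self, rng):
        for _ in range(20):
            x = rng.normal(96, 0.5, int(rng.integers(10, 150))).round(1)
            assert central_tendency_measure(x, 0.25) == pytest.approx(
                oracles.ctm_bruteforce(x, 0.25), abs=1e-12
            )


class TestARSpectrum:
    def test_burg_matches_statsmodels(self, rng):
        """Burg sweep agrees with the statsmodels implementation per order."""
        sm = pytest.importorskip("statsmodels.regression.linear_model")
        for _ in range(5):
            x = lfilter([1.0], [1.0, -0.6, 0.2], rng.standard_normal(400))
            x = x - x.mean()
            coeffs, variances = ar.burg_sweep(x, 6)
            for p in (2, 4, 6):
                rho, _ = sm.burg(x, p, demean=False)
                np.testing.assert_allclose(coeffs[p], -rho, atol=1e-10)

    def test_psd_internal_consistency(self, rng):
        """The stored grid equals the PSD re-evaluated from (a, sigma2, T)."""
        spec = fit_ar_psd(rng.normal(96, 1, 120))
        np.testing.assert_array_equal(
            spec.psd, ar.evaluate_ar_psd(spec.coeffs, spec.sigma2, spec.T, spec.freqs)
        )
        assert np.all(spec.psd > 0)

    def test_white_noise_flat_psd(self, rng):
        """White noise selects a tiny order; PSD ~ flat at 2*sigma^2*T."""
        levels = []
        for _ in range(30):
            x = rng.standard_normal(512)
            spec = fit_ar_psd(x, T=1.0, max_order=20)
            assert spec.order <= 3
            levels.append(spec.psd / (2 * x.var() * 1.0))
        mean_level = np.mean(levels, axis=0)
        assert np.all(np.abs(mean_level - 1.0) < 0.25)

    def test_ar4_peak_recovered(self, rng):
        """A planted 0.03 Hz spectral peak is located within +-0.005 Hz."""
        r, th = 0.97, 2 * np.pi * 0.03
        den = np.real(np.poly([r * np.exp(1j * th), r * np.exp(-1j * th), 0.5, -0.3]))
        for _ in range(5):
            x = lfilter([1.0], den, rng.standard_normal(4000))
            spec = fit_ar_psd(x, T=1.0, max_order=30)
            peak = spec.freqs[np.argmax(spec.psd)]
            assert abs(peak - 0.03) <= 0.005

    def test_psd_integral_approximates_variance(self, rng):
        """Integral of the one-sided PSD ~ signal variance (within 10%)."""
        den = np.real(np.poly([0.8, -0.5, 0.3 + 0.4j, 0.3 - 0.4j]))
        for _ in range(5):
            x = lfilter([1.0], den, rng.standard_normal(5000))
            spec = fit_ar_psd(x, T=1.0, max_order=30)
            assert ar.total_power(spec) == pytest.approx(np.var(x), rel=0.10)


class TestModulationBand:
    def test_sinusoid_dominates_band(self, rng):
        t = np.arange(120.0)
        x = 96 + 1.5 * np.sin(2 * np.pi * 0.03 * t) + 0.05 * rng.standard_normal(120)
        spec = fit_ar_psd(x)
        P, R, SE, mod_freq = modulation_band_features(spec)
        assert abs(mod_freq - 0.03) <= 0.005
        assert R > 0.5

    def test_flat_spectrum_entropy_and_ratio(self):
        """On a flat 256-bin spectrum SE ~ 8 bits and R ~ bandwidth fraction."""
        freqs = 0.5 * np.arange(1, 257) / 256
        flat = ar.ARSpectrum(np.zeros(0), 1.0, 0, 1.0, freqs, np.ones(256))
        P, R, SE, mod_freq = modulation_band_features(flat)
        assert SE == pytest.approx(8.0, abs=1e-9)
        width = (min(mod_freq + 0.01, 0.1) - max(mod_freq - 0.01, 0.005))
        assert R == pytest.approx(width / 0.5, rel=0.02)

    def test_single_bin_spectrum_zero_entropy(self):
        freqs = 0.5 * np.arange(1, 257) / 256
        psd = np.zeros(256)
        psd[10] = 5.0  # f ~ 0.0215 Hz, inside the modulation band
        spec = ar.ARSpectrum(np.zeros(0), 1.0, 0, 1.0, freqs, psd)
        P, R, SE, mod_freq = modulation_band_features(spec)
        assert SE == 0.0
        assert mod_freq == pytest.approx(freqs[10])

    def test_ratio_scale_invariant_power_quadratic(self, rng):
        """R is invariant under x -> a*x; P scales with a^2."""
        t = np.arange(120.0)
        x = 96 + np.sin(2 * np.pi * 0.03 * t) + 0.1 * rng.standard_normal(120)
        x = x - x.mean()
        for a in (2.0, 7.5):
            s1 = fit_ar_psd(x)
            s2 = fit_ar_psd(a * x)
            P1, R1, *_ = modulation_band_features(s1)
            P2, R2, *_ = modulation_band_features(s2)
            assert R2 == pytest.approx(R1, rel=1e-6)
            assert P2 == pytest.approx(a * a * P1, rel=1e-6)


class TestWindowFeatures:
    def test_invalid_when_heavily_masked(self):
        x = np.full(120, 96.0)
        mask = np.zeros(120, bool)
        mask[:30] = True  # 25% > 20% limit
        feats = spo2_window_features(x, mask)
        assert not feats.valid

    def test_gap_interpolation_policy(self):
        x = np.full(120, 96.0)
        x[50:54] = np.nan
        assert interpolate_gaps(x, max_gap_s=5.0) is not None
        x[60:70] = np.nan
        assert interpolate_gaps(x, max_gap_s=5.0) is None

    def test_full_window_is_valid_and_finite(self, rng):
        x = np.round(rng.normal(96, 0.5, 120), 1)
        feats = spo2_window_features(x, np.zeros(120, bool))
        assert feats.valid
        for name in ("mean", "std", "iqr", "delta_index", "ctm", "apen", "P", "R", "SE"):
            assert np.isfinite(getattr(feats, name)), name
        assert 0.005 <= feats.mod_freq <= 0.1
        assert 0 <= feats.R <= 1
        assert 0 <= feats.SE <= 8
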
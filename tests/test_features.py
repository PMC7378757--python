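import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fallkit as fk
from fallkit.features import (
    AXIS_FEATURE_NAMES,
    DEFAULT_BANDS,
    FEATURE_NAMES,
    iterative_peak_search,
)


def brute_force_moments(x):
    """Direct summation oracle for the population moment definitions."""
    n = len(x)
    mu = math.fsum(x) / n
    var = math.fsum((v - mu) ** 2 for v in x) / n
    std = math.sqrt(var)
    rms = math.sqrt(math.fsum(abs(v) ** 2 for v in x) / n)
    if std == 0:
        return mu, var, std, rms, 0.0, 0.0
    skew = math.fsum((v - mu) ** 3 for v in x) / (n * std**3)
    kurt = math.fsum((v - mu) ** 4 for v in x) / (n * std**4)
    return mu, var, std, rms, skew, kurt


class TestSpatialStatistics:
    def test_constant_channel_degenerate_convention(self):
        out = fk.spatial_statistics(np.full(101, 2.5))
        assert out == (2.5, 0.0, 0.0, 2.5, 0.0, 0.0)

    def test_three_point_example(self):
        mu, var, std, rms, skew, kurt = fk.spatial_statistics(np.array([1.0, 2.0, 3.0]))
        assert mu == pytest.approx(2.0)
        assert var == pytest.approx(2 / 3)
        assert std == pytest.approx(0.8164966, abs=1e-6)
        assert rms == pytest.approx(2.1602469, abs=1e-6)
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert kurt == pytest.approx(1.5)

    def test_gaussian_kurtosis_limit(self):
        x = np.random.default_rng(1234).standard_normal(100_000)
        assert fk.spatial_statistics(x)[5] == pytest.approx(3.0, abs=0.05)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=2,
            max_size=64,
        )
    )
    def test_matches_brute_force_oracle(self, values):
        ours = fk.spatial_statistics(np.array(values))
        oracle = brute_force_moments(values)
        assert ours == pytest.approx(oracle, abs=1e-12, rel=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fk.spatial_statistics(np.array([1.0]))


class TestAutocorrelation:
    @pytest.mark.parametrize("freq", [2.0, 5.0, 8.0, 12.0])
    def test_sinusoid_period_recovered_within_one_lag(self, freq):
        fs = 50.0
        x = np.sin(2 * np.pi * freq * np.arange(101) / fs)
        main_pos, second_pos, second_amp = fk.autocorrelation_features(x, fs)
        assert main_pos == 0.0
        assert second_pos == pytest.approx(1.0 / freq, abs=1.0 / fs)
        assert second_amp > 0.5

    def test_zero_signal_degenerate(self):
        assert fk.autocorrelation_features(np.zeros(101), 50.0) == (0.0, 0.0, 0.0)

    def test_white_noise_second_peak_small(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(101)
            _, _, amp = fk.autocorrelation_features(x, 50.0)
            hits += amp < 0.5
        assert hits >= 99


class TestWelchPsd:
    def test_zero_signal_zero_density(self):
        psd = fk.welch_psd(np.zeros(101), 50.0)
        assert np.all(psd.densities == 0.0)

    def test_white_noise_power_integral(self):
        x = np.random.default_rng(7).standard_normal(4096)
        psd = fk.welch_psd(x, 50.0)
        total = np.trapezoid(psd.densities, psd.frequencies)
        assert total == pytest.approx(x.var() + x.mean() ** 2, rel=0.2)

    def test_sinusoid_argmax_within_one_bin(self):
        fs = 50.0
        x = np.sin(2 * np.pi * 5.0 * np.arange(101) / fs)
        psd = fk.welch_psd(x, fs)
        df = psd.frequencies[1] - psd.frequencies[0]
        peak_freq = psd.frequencies[np.argmax(psd.densities)]
        assert abs(peak_freq - 5.0) <= df

    def test_grid_spans_zero_to_nyquist(self):
        psd = fk.welch_psd(np.random.default_rng(0).standard_normal(101), 50.0)
        assert psd.frequencies[0] == 0.0
        assert psd.frequencies[-1] == 25.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fk.welch_psd(np.ones(5), 50.0)


class TestSpectralPeaks:
    def test_all_zero_psd_pads_with_zeros(self):
        psd = fk.PsdEstimate(np.linspace(0, 25, 32), np.zeros(32))
        assert np.array_equal(fk.spectral_peak_features(psd), np.zeros(12))

    def test_two_tone_amplitude_ordering(self):
        f = np.linspace(0, 25, 512)
        d = np.exp(-((f - 3.0) ** 2) / 0.05) + 0.5 * np.exp(-((f - 8.0) ** 2) / 0.05)
        out = fk.spectral_peak_features(fk.PsdEstimate(f, d))
        assert out[0] == pytest.approx(3.0, abs=0.1)
        assert out[1] == pytest.approx(8.0, abs=0.1)
        assert out[6] > out[7] > 0

    def test_single_tone_with_flat_floor(self):
        f = np.linspace(0, 25, 256)
        d = np.exp(-((f - 5.0) ** 2) / 0.1)
        out = fk.spectral_peak_features(fk.PsdEstimate(f, d))
        assert out[0] == pytest.approx(5.0, abs=0.1)
        # padded slots are zero
        assert np.count_nonzero(out[6:]) == 1

    def test_exclusion_radius_suppresses_shoulder_bins(self):
        values = np.array([0.0, 1.0, 10.0, 9.0, 1.0, 0.0])
        peaks = iterative_peak_search(values, np.arange(6.0), min_distance=1.0, max_peaks=6)
        positions = [p for p, _ in peaks]
        assert positions[0] == 2.0
        assert 3.0 not in positions


class TestBandPowers:
    def test_zero_psd(self):
        psd = fk.PsdEstimate(np.linspace(0, 25, 64), np.zeros(64))
        assert np.array_equal(fk.band_powers(psd), np.zeros(3))

    def test_flat_psd_bandwidth_ratio(self):
        psd = fk.PsdEstimate(np.linspace(0, 25, 2048), np.ones(2048))
        assert fk.band_powers(psd) == pytest.approx([4.5, 5.0, 10.0], rel=1e-6)

    def test_sinusoid_power_lands_in_its_band(self):
        fs, amp = 50.0, 2.0
        x = amp * np.sin(2 * np.pi * 7.0 * np.arange(8192) / fs)
        powers = fk.band_powers(fk.welch_psd(x, fs))
        assert powers[1] == pytest.approx(amp**2 / 2, rel=0.1)
        assert powers[0] < 0.05 * powers[1]
        assert powers[2] < 0.05 * powers[1]

    def test_insufficient_coverage_rejected(self):
        psd = fk.PsdEstimate(np.linspace(0, 10, 64), np.ones(64))
        with pytest.raises(ValueError, match="coverage"):
            fk.band_powers(psd)

    def test_default_bands(self):
        assert DEFAULT_BANDS == ((0.5, 5.0), (5.0, 10.0), (10.0, 20.0))


class TestFeatureVectorAssembly:
    def test_72_values_with_27_spatial_and_45_frequency(self, small_segments):
        fv = fk.extract_event_features(small_segments[0])
        assert fv.values.shape == (72,)
        spatial = [n for n in fv.names if n.split(".")[0] in AXIS_FEATURE_NAMES[:9]]
        assert len(spatial) == 27
        assert len(fv.names) - len(spatial) == 45

    def test_interleaved_name_order_sentinel(self, make_segment):
        seg = make_segment(np.ones(101), 2 * np.ones(101), 3 * np.ones(101))
        fv = fk.extract_event_features(seg)
        assert fv.names[:3] == ("mean.x", "mean.y", "mean.z")
        assert fv.values[0] == 1.0 and fv.values[1] == 2.0 and fv.values[2] == 3.0

    def test_name_order_fixed_across_events(self, small_segments):
        vectors = [fk.extract_event_features(s) for s in small_segments[:5]]
        assert all(v.names == FEATURE_NAMES for v in vectors)

    def test_identical_segments_give_bit_identical_vectors(self, small_segments):
        a = fk.extract_event_features(small_segments[0])
        b = fk.extract_event_features(small_segments[0])
        assert np.array_equal(a.values, b.values)

    def test_non_negative_dispersion_features(self, small_segments):
        nonneg_prefixes = ("variance", "std", "rms", "psd_peak", "bandpower")
        for seg in small_segments[:10]:
            fv = fk.extract_event_features(seg)
            for name, value in zip(fv.names, fv.values):
                if name.startswith(nonneg_prefixes) and "pos" not in name:
                    assert value >= 0, name


class TestTotalAcceleration:
    def test_constant_unit_vector(self, make_segment):
        seg = make_segment(np.zeros(101), np.zeros(101), np.ones(101))
        fv = fk.total_acceleration_features(seg)
        assert tuple(fv.values) == (1.0, 1.0)

    def test_three_four_five_spike(self, make_segment):
        x, y, z = np.zeros(101), np.zeros(101), np.zeros(101)
        x[50], y[50] = 3.0, 4.0
        fv = fk.total_acceleration_features(make_segment(x, y, z))
        assert tuple(fv.values) == (0.0, 5.0)

    def test_min_never_exceeds_max(self, small_segments):
        for seg in small_segments:
            lo, hi = fk.total_acceleration_features(seg).values
            assert lo <= hi
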
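import numpy as np
import pytest

from ecgkit.denoise import (
    ButterworthLowPass,
    Gaussian,
    Median,
    MovingAverage,
    SavitzkyGolay,
    Wavelet,
    apply_filter,
    butterworth_lowpass,
    default_filter_bank,
    gaussian_filter,
    median_filter,
    moving_average_filter,
    savgol_filter,
    wavelet_denoise,
)
from ecgkit.synthetic_ecg import NoiseSpec, SimulationConfig, add_noise, generate_clean_ecg

from .oracles import gaussian_convolution, savgol_per_window, sliding_mean, sliding_median


class TestMedian:
    def test_impulse_removal(self):
        np.testing.assert_array_equal(
            median_filter([1, 1, 9, 1, 1], 3), [1, 1, 1, 1, 1]
        )

    def test_constant_unchanged(self):
        np.testing.assert_array_equal(median_filter(np.full(77, 3.5), 5), np.full(77, 3.5))

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            x = rng.standard_normal(500)
            np.testing.assert_array_equal(median_filter(x, 5), sliding_median(x, 5))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            median_filter(np.zeros(10), 4)


class TestMovingAverage:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(moving_average_filter(np.full(50, 2.0), 5), 2.0)

    def test_small_example(self):
        assert moving_average_filter([0.0, 3.0, 0.0], 3)[1] == pytest.approx(1.0)

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            x = rng.standard_normal(500)
            np.testing.assert_allclose(
                moving_average_filter(x, 5), sliding_mean(x, 5), atol=1e-12
            )

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            moving_average_filter(np.zeros(3), 5)


class TestGaussian:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(gaussian_filter(np.full(60, -1.5), 2.0), -1.5)

    def test_impulse_response_is_kernel(self):
        x = np.zeros(101)
        x[50] = 1.0
        out = gaussian_filter(x, 2.0, truncate=4.0)
        radius = int(4.0 * 2.0 + 0.5)
        t = np.arange(-radius, radius + 1)
        kernel = np.exp(-0.5 * (t / 2.0) ** 2)
        kernel /= kernel.sum()
        np.testing.assert_allclose(out[50 - radius : 50 + radius + 1], kernel, atol=1e-12)

    def test_matches_dense_convolution(self, rng):
        for _ in range(20):
            x = rng.standard_normal(500)
            np.testing.assert_allclose(
                gaussian_filter(x, 2.0, 4.0), gaussian_convolution(x, 2.0, 4.0), atol=1e-10
            )

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            gaussian_filter(np.zeros(10), 0.0)


class TestSavitzkyGolay:
    def test_reproduces_low_degree_polynomials(self):
        t = np.linspace(-1, 1, 200)
        coeffs = np.array([0.3, -1.2, 0.7, 2.0, -0.5, 1.1, 0.2, -0.8])
        x = np.polynomial.polynomial.polyval(t, coeffs)  # degree 7
        np.testing.assert_allclose(savgol_filter(x, 25, 7), x, atol=1e-8)

    def test_constant_unchanged(self):
        np.testing.assert_allclose(savgol_filter(np.full(60, 4.0), 25, 7), 4.0, atol=1e-10)

    def test_matches_per_window_least_squares(self, rng):
        for _ in range(5):
            x = rng.standard_normal(500)
            np.testing.assert_allclose(
                savgol_filter(x, 25, 7), savgol_per_window(x, 25, 7), atol=1e-8
            )

    def test_polyorder_must_be_below_window(self):
        with pytest.raises(ValueError, match="polyorder"):
            savgol_filter(np.zeros(100), 25, 25)


class TestButterworth:
    def test_dc_unchanged(self):
        out = butterworth_lowpass(np.full(2000, 1.0), 4, 40.0, 360.0)
        np.testing.assert_allclose(out[500:1500], 1.0, atol=1e-6)

    def test_single_pass_gain_at_cutoff(self):
        # defining property: -3 dB (1/sqrt(2)) at the cutoff frequency
        fs, fc = 360.0, 40.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * fc * t)
        y = butterworth_lowpass(x, 4, fc, fs, zero_phase=False)
        steady = slice(int(5 * fs), None)
        gain = np.sqrt(np.mean(y[steady] ** 2) / np.mean(x[steady] ** 2))
        assert gain == pytest.approx(1.0 / np.sqrt(2.0), rel=0.01)

    def test_stopband_attenuation_passband_preservation(self):
        fs = 360.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 120 * t)
        y = butterworth_lowpass(x, 4, 40.0, fs)
        spectrum = np.abs(np.fft.rfft(y)) / (len(y) / 2)
        freqs = np.fft.rfftfreq(len(y), 1 / fs)
        amp_10 = spectrum[np.argmin(np.abs(freqs - 10))]
        amp_120 = spectrum[np.argmin(np.abs(freqs - 120))]
        assert amp_10 == pytest.approx(1.0, rel=0.05)
        assert 20 * np.log10(amp_120 / 1.0) < -30
    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            butterworth_lowpass(np.zeros(100), 4, 200.0, 360.0)


class TestWaveletDenoise:
    def test_zero_signal_maps_to_zero(self):
        np.testing.assert_array_equal(wavelet_denoise(np.zeros(1024)), np.zeros(1024))

    def test_non_expansive(self, noisy_pair_10s):
        _, noisy = noisy_pair_10s
        out = wavelet_denoise(noisy)
        assert np.linalg.norm(out) <= np.linalg.norm(noisy) * (1 + 1e-9)

    def test_reduces_mse_on_noisy_ecg(self):
        for seed in range(5):
            clean = generate_clean_ecg(SimulationConfig(duration=10.0, seed=seed)).channel()
            noisy = add_noise(clean, NoiseSpec(snr_db=10.0, seed=seed + 100))
            denoised = wavelet_denoise(noisy)
            assert np.mean((denoised - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            wavelet_denoise(np.zeros(8))


class TestApplyFilter:
    def test_dispatch_matches_direct_call(self, noisy_pair_10s):
        _, noisy = noisy_pair_10s
        np.testing.assert_array_equal(
            apply_filter(noisy, Median(3)), median_filter(noisy, 3)
        )
        np.testing.assert_array_equal(
            apply_filter(noisy, SavitzkyGolay()), savgol_filter(noisy)
        )

    def test_dispatch_example(self):
        np.testing.assert_array_equal(
            apply_filter(np.array([1.0, 1, 9, 1, 1]), Median(3)), [1, 1, 1, 1, 1]
        )

    @pytest.mark.parametrize("name", sorted(default_filter_bank()))
    def test_length_preserved_and_input_unmutated(self, name, rng):
        config = default_filter_bank()[name]
        x = rng.standard_normal(2160)
        before = x.copy()
        out = apply_filter(x, config, sampling_rate=360.0)
        assert out.shape == (2160,)
        np.testing.assert_array_equal(x, before)

    def test_unknown_config_rejected(self):
        with pytest.raises(TypeError):
            apply_filter(np.zeros(10), object())


class TestDefaultsImproveNoisySignal:
    def test_all_filters_beat_noisy_baseline_on_average(self):
        # premise of the PSNR comparison: denoising helps at 10 dB SNR
        from ecgkit.metrics import psnr

        gains = {name: [] for name in default_filter_bank()}
        for seed in range(5):
            clean = generate_clean_ecg(SimulationConfig(duration=10.0, seed=seed)).channel()
            noisy = add_noise(clean, NoiseSpec(snr_db=10.0, seed=seed + 50))
            base = psnr(clean, noisy)
            for name, config in default_filter_bank().items():
                gains[name].append(psnr(clean, apply_filter(noisy, config)) - base)
        for name, deltas in gains.items():
            assert np.mean(deltas) > 0, f"{name} did not improve PSNR"
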
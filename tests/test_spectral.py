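"""Multitaper spectral estimation against independent oracles."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from seizlfp.core import ParameterError, Recording
from seizlfp.spectral import (
    band_power,
    band_power_change,
    dpss_tapers,
    multitaper_spectrogram,
    multitaper_spectrum,
    smooth_spectrum,
)


class TestTapers:
    def test_orthonormality(self):
        tapers, _ = dpss_tapers(2500, nw=3, k=5)
        gram = tapers @ tapers.T
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)

    def test_concentrations_sorted_and_first_above_099(self):
        _, lam = dpss_tapers(2500, nw=3, k=5)
        assert lam[0] > 0.99
        assert np.all(np.diff(lam) <= 0)
        assert np.all(lam > 0)

    def test_first_taper_has_no_sign_changes(self):
        tapers, _ = dpss_tapers(2500, nw=3, k=5)
        first = tapers[0][np.abs(tapers[0]) > 1e-12]
        assert np.all(first > 0) or np.all(first < 0)

    def test_taper_count_bound_enforced(self):
        with pytest.raises(ParameterError):
            dpss_tapers(100, nw=3, k=6)


class TestSpectrum:
    def test_sinusoid_peak_and_bandwidth(self):
        fs, dur = 1000.0, 2.5
        t = np.arange(int(fs * dur)) / fs
        est = multitaper_spectrum(np.sin(2 * np.pi * 10 * t), fs)
        f_peak = est.freqs[np.argmax(est.power)]
        grid = est.freqs[1] - est.freqs[0]
        assert abs(f_peak - 10.0) <= grid / 2 + 1e-12
        # half-power width ~ 2 NW / T = 2.4 Hz for NW=3, T=2.5 s
        half = est.power.max() / 2
        above = est.freqs[est.power >= half]
        width = above.max() - above.min()
        assert 1.2 <= width <= 4.8

    def test_no_padding_means_nfft_equals_n(self):
        est = multitaper_spectrum(np.random.default_rng(0).normal(size=2500), 1000.0)
        assert est.params["nfft"] == 2500
        assert est.freqs[1] - est.freqs[0] == pytest.approx(1000.0 / 2500)

    def test_zero_signal_all_power_zero(self):
        est = multitaper_spectrum(np.zeros(1000), 1000.0)
        assert np.all(est.power == 0)
        assert np.all(np.isfinite(est.power_db))  # dB floor applied

    def test_parseval_variance_within_10pct(self, rng):
        x = rng.standard_normal(10000)
        est = multitaper_spectrum(x, 1000.0)
        df = est.freqs[1] - est.freqs[0]
        assert np.sum(est.power) * df == pytest.approx(np.var(x), rel=0.10)

    def test_rectangular_taper_reduces_to_periodogram(self, rng):
        x = rng.standard_normal(2048)
        fs = 1000.0
        rect = np.ones((1, x.size)) / np.sqrt(x.size)
        est = multitaper_spectrum(x, fs, tapers=rect)
        f_ref, p_ref = sp_signal.periodogram(x, fs, detrend=False)
        np.testing.assert_allclose(est.freqs, f_ref, atol=1e-12)
        np.testing.assert_allclose(est.power, p_ref, atol=1e-9)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ParameterError):
            multitaper_spectrum(np.zeros(8), 1000.0, k=5)


class TestSpectrogram:
    def test_slice_count(self, rng):
        rec = Recording(samples=rng.standard_normal(10000), fs=1000.0)
        gram = multitaper_spectrogram(rec, window_s=2.5, step_s=0.05)
        expected = int(np.floor((10.0 - 2.5) / 0.05)) + 1
        assert gram.times.size == expected
        assert np.allclose(np.diff(gram.times), 0.05)

    def test_stationary_noise_slices_agree(self, rng):
        rec = Recording(samples=rng.standard_normal(10000), fs=1000.0)
        gram = multitaper_spectrogram(rec, window_s=2.5, step_s=0.5)
        slice_db = 10 * np.log10(gram.power.mean(axis=1))
        assert np.all(np.abs(slice_db - slice_db.mean()) < 2.0)

    def test_chirp_peak_frequency_nondecreasing(self):
        fs = 1000.0
        t = np.arange(int(20 * fs)) / fs
        x = sp_signal.chirp(t, f0=5, f1=40, t1=20, method="linear")
        gram = multitaper_spectrogram(
            Recording(samples=x, fs=fs), window_s=2.5, step_s=1.0
        )
        peaks = gram.freqs[np.argmax(gram.power, axis=1)]
        assert np.all(np.diff(peaks) >= -1e-9)

    def test_short_recording_rejected(self):
        rec = Recording(samples=np.zeros(1000), fs=1000.0)
        with pytest.raises(ParameterError):
            multitaper_spectrogram(rec, window_s=2.5)


class TestSmoothing:
    def test_window_one_is_identity(self, rng):
        est = multitaper_spectrum(rng.standard_normal(2000), 1000.0)
        smoothed, sd = smooth_spectrum(est, window_bins=1)
        np.testing.assert_allclose(smoothed, est.power)
        assert np.all(sd == 0)

    def test_constant_power_smooths_to_itself(self):
        from seizlfp.spectral import SpectralEstimate

        est = SpectralEstimate(
            freqs=np.linspace(0, 500, 200), power=np.full(200, 3.0), params={}
        )
        smoothed, sd = smooth_spectrum(est, window_bins=50)
        np.testing.assert_allclose(smoothed, 3.0)
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_delta_spike_spreads_by_window(self):
        from seizlfp.spectral import SpectralEstimate

        power = np.full(500, 1.0)
        power[250] += 50.0
        est = SpectralEstimate(freqs=np.arange(500.0), power=power, params={})
        smoothed, _ = smooth_spectrum(est, window_bins=50)
        assert smoothed[250] == pytest.approx(1.0 + 50.0 / 50.0, rel=1e-9)

    def test_oversized_window_rejected(self):
        from seizlfp.spectral import SpectralEstimate

        est = SpectralEstimate(freqs=np.arange(10.0), power=np.ones(10), params={})
        with pytest.raises(ParameterError):
            smooth_spectrum(est, window_bins=11)


class TestBandPower:
    def test_flat_spectrum_any_band(self):
        from seizlfp.spectral import SpectralEstimate

        est = SpectralEstimate(
            freqs=np.linspace(0, 500, 501), power=np.full(501, 10.0), params={}
        )
        for band in [(1, 4), (12, 30), (100, 400)]:
            assert band_power(est, band) == pytest.approx(10.0, abs=1e-9)

    def test_doubling_power_adds_3db(self, rng):
        est = multitaper_spectrum(rng.standard_normal(2500), 1000.0)
        from seizlfp.spectral import SpectralEstimate

        doubled = SpectralEstimate(
            freqs=est.freqs, power=2 * est.power, params=est.params
        )
        assert band_power(doubled, (1, 4)) - band_power(est, (1, 4)) == pytest.approx(
            10 * np.log10(2), abs=1e-9
        )

    def test_band_above_nyquist_rejected(self, rng):
        est = multitaper_spectrum(rng.standard_normal(1000), 1000.0)
        with pytest.raises(ParameterError):
            band_power(est, (600, 700))


class TestBandPowerChange:
    def test_identical_periods_are_100pct(self, rng):
        rec = Recording(samples=rng.standard_normal(20000), fs=1000.0)
        change = band_power_change(rec, (0, 10), (0, 10), (1, 4))
        assert change.pct_of_baseline == pytest.approx(100.0, abs=1e-9)

    def test_overlapping_periods_rejected(self, rng):
        rec = Recording(samples=rng.standard_normal(20000), fs=1000.0)
        with pytest.raises(ParameterError, match="overlap"):
            band_power_change(rec, (0, 10), (5, 15), (1, 4))

    def test_doubled_beta_component_reads_near_200pct(self, rng):
        # band-filling 12-30 Hz noise whose power doubles in period 2
        fs, half = 1000.0, 30.0
        n = int(fs * half)
        sos = sp_signal.butter(4, [12 / 500, 30 / 500], btype="bandpass",
                               output="sos")
        beta = sp_signal.sosfiltfilt(sos, rng.standard_normal(2 * n + 20000))
        beta = beta[10000:-10000] / beta.std()
        beta[n:] *= np.sqrt(2)
        x = beta + 0.05 * rng.standard_normal(2 * n)
        rec = Recording(samples=x, fs=fs)
        change = band_power_change(rec, (0, half), (half, 2 * half), (12, 30))
        assert change.pct_of_baseline == pytest.approx(200.0, rel=0.15)
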
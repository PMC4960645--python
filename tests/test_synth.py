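"""Simulator contracts: determinism, presets, recovery, spectral contrast."""

import numpy as np
import pytest

from seizlfp.core import ParameterError
from seizlfp.events import baseline_stats, detect_events
from seizlfp.preprocess import remove_line_noise, resample_to
from seizlfp.spectral import band_power, multitaper_spectrum
from seizlfp.synth import (
    SynthConfig,
    generate_background,
    generate_event_train,
    generate_paired_recording,
    inject_events,
    preset,
)


class TestPresets:
    def test_presets_encode_published_statistics(self):
        a100 = preset("anaesthetized_100uM")
        assert a100.amp_mean_mv == 1.64 and a100.amp_sd_mv == 0.67
        assert a100.interval_mean_s == 1.01 and a100.interval_sd_s == 0.88
        assert a100.onset_min_mean == 10.31 and a100.cessation_min_mean == 32.83
        a250 = preset("anaesthetized_250uM")
        assert a250.onset_min_mean == 5.16 and a250.cessation_min_mean == 47.50
        awake = preset("awake_100uM")
        assert awake.amp_mean_mv == 1.4 and awake.interval_mean_s == 0.83
        assert awake.state == "awake"

    def test_control_has_no_events(self):
        cfg = preset("control", fs_lfp=500.0, duration_s=400.0)
        times, amps, onset, cess = generate_event_train(cfg)
        assert times.size == 0 and onset is None

    def test_unknown_preset_rejected(self):
        with pytest.raises(ParameterError):
            preset("anaesthetized_1mM")


class TestBackground:
    def test_overall_sd_near_requested(self):
        cfg = SynthConfig(duration_s=120.0, fs_lfp=1000.0, noise_sd_mv=0.1, seed=3)
        bg = generate_background(cfg)
        assert np.std(bg) == pytest.approx(0.1, rel=0.10)

    def test_anaesthetized_delta_dominates_awake_by_6db(self):
        kw = dict(duration_s=120.0, fs_lfp=1000.0, seed=3)
        anesth = generate_background(SynthConfig(state="anaesthetized", **kw))
        awake = generate_background(SynthConfig(state="awake", **kw))
        d_anesth = band_power(multitaper_spectrum(anesth, 1000.0), (1, 4))
        d_awake = band_power(multitaper_spectrum(awake, 1000.0), (1, 4))
        assert d_anesth - d_awake >= 6.0

    def test_determinism_and_seed_sensitivity(self):
        kw = dict(duration_s=30.0, fs_lfp=1000.0)
        a = generate_background(SynthConfig(seed=5, **kw))
        b = generate_background(SynthConfig(seed=5, **kw))
        c = generate_background(SynthConfig(seed=6, **kw))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


class TestEventTrain:
    def test_times_strictly_increasing_gaps_positive(self):
        cfg = preset("anaesthetized_100uM", fs_lfp=1000.0, duration_s=2400.0,
                     application_time_s=300.0, seed=11)
        times, amps, onset, cess = generate_event_train(cfg)
        assert times.size > 10
        assert np.all(np.diff(times) > 0)
        assert np.all(amps > 0)
        assert onset is not None and cess is not None and cess > onset

    def test_amplitude_parameter_recovered_over_seeds(self):
        # post-ramp amplitudes should center on the generating 1.64 mV
        means = []
        for seed in range(50):
            cfg = preset(
                "anaesthetized_100uM", fs_lfp=1000.0, duration_s=2400.0,
                application_time_s=300.0, onset_min_sd=1.0, seed=seed,
            )
            _, amps, _, _ = generate_event_train(cfg)
            if amps.size < 20:
                continue
            n_ramp = int(np.ceil(cfg.buildup_fraction * amps.size))
            means.append(np.mean(amps[n_ramp:]))
        assert np.mean(means) == pytest.approx(1.64, rel=0.10)

    def test_buildup_ramps_from_one_fifth(self):
        cfg = preset("anaesthetized_100uM", fs_lfp=1000.0, duration_s=2400.0,
                     application_time_s=300.0, amp_sd_mv=0.0, seed=2)
        _, amps, _, _ = generate_event_train(cfg)
        n_ramp = int(np.ceil(cfg.buildup_fraction * amps.size))
        assert amps[0] == pytest.approx(0.2 * 1.64, rel=1e-6)
        np.testing.assert_allclose(amps[n_ramp:], 1.64, rtol=1e-9)


class TestInjection:
    def test_negative_peak_at_event_time(self):
        bg = np.zeros(10_000)
        out = inject_events(bg, np.array([5.0]), np.array([1.3]), 40.0, fs=1000.0)
        assert out.min() == pytest.approx(-1.3, rel=1e-6)
        assert abs(np.argmin(out) - 5000) <= 1

    def test_zero_amplitude_leaves_trace(self):
        bg = np.zeros(5000)
        out = inject_events(bg, np.array([2.0]), np.array([0.0]), 40.0, fs=1000.0)
        np.testing.assert_array_equal(out, bg)

    def test_event_outside_trace_rejected(self):
        with pytest.raises(ParameterError):
            inject_events(np.zeros(100), np.array([15.0]), np.array([1.0]), 40.0,
                          fs=10.0)

    def test_injected_event_recovered_by_detector(self, rng):
        fs = 1000.0
        noise = rng.standard_normal(int(320 * fs)) * 0.1
        out = inject_events(noise, np.array([310.0]), np.array([1.0]), 40.0, fs=fs)
        from seizlfp.core import Recording

        rec = Recording(samples=out, fs=fs)
        ev = detect_events(rec, baseline_stats(rec, 300.0))
        assert len(ev) == 1
        assert abs(ev.times[0] - 310.0) <= 0.005


class TestEngCoupling:
    def test_full_coupling_one_cap_per_event(self):
        cfg = preset("anaesthetized_100uM", fs_lfp=1000.0, fs_eng=2000.0,
                     duration_s=1500.0, application_time_s=300.0, seed=4,
                     couple_prob=1.0)
        _, _, truth = generate_paired_recording(cfg)
        assert truth.eng_cap_times_s.size == truth.event_times_s.size
        lat = truth.eng_cap_times_s - truth.event_times_s
        assert np.all(lat >= 0) and np.all(lat <= 0.2)

    def test_no_coupling_no_caps(self):
        cfg = preset("anaesthetized_100uM", fs_lfp=1000.0, fs_eng=2000.0,
                     duration_s=1500.0, application_time_s=300.0, seed=4,
                     couple_prob=0.0)
        _, _, truth = generate_paired_recording(cfg)
        assert truth.eng_cap_times_s.size == 0

    def test_half_coupling_fraction_concentrates(self):
        cfg = preset(
            "anaesthetized_100uM", fs_lfp=200.0, fs_eng=400.0,
            duration_s=3000.0, application_time_s=300.0, seed=4,
            couple_prob=0.5, onset_min_sd=0.1, onset_min_mean=0.5,
            cessation_min_mean=44.0, cessation_min_sd=0.1,
            interval_mean_s=1.0, interval_sd_s=0.2,
        )
        _, _, truth = generate_paired_recording(cfg)
        assert truth.coupled_flags.size > 1500
        assert np.mean(truth.coupled_flags) == pytest.approx(0.5, abs=0.03)


class TestPairedRecording:
    def test_bit_identical_for_same_seed(self):
        cfg = preset("anaesthetized_100uM", fs_lfp=500.0, fs_eng=1000.0,
                     duration_s=900.0, application_time_s=300.0, seed=9)
        lfp1, eng1, truth1 = generate_paired_recording(cfg)
        lfp2, eng2, truth2 = generate_paired_recording(cfg)
        np.testing.assert_array_equal(lfp1.samples, lfp2.samples)
        np.testing.assert_array_equal(eng1.samples, eng2.samples)
        np.testing.assert_array_equal(truth1.event_times_s, truth2.event_times_s)

    def test_control_truth_empty_and_marker_set(self):
        cfg = preset("control", fs_lfp=1000.0, duration_s=700.0, seed=2)
        lfp, eng, truth = generate_paired_recording(cfg)
        assert truth.event_times_s.size == 0
        assert lfp.markers["application"] == cfg.application_time_s
        assert lfp.kind == "LFP" and eng.kind == "ENG"

    def test_end_to_end_event_count_within_10pct(self, fast_anaesthetized):
        lfp, _, truth = generate_paired_recording(fast_anaesthetized)
        working = resample_to(remove_line_noise(lfp, (50, 60)), 1000.0)
        ev = detect_events(working, baseline_stats(working, 300.0))
        assert len(ev) == pytest.approx(truth.event_times_s.size, rel=0.10)
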
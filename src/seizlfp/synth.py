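"""Synthetic paired LFP/ENG recordings with known ground truth.

The generator emulates the signal structure the analysis pipeline
assumes, so every stage can be validated without the original in vivo
recordings:

* 1/f-shaped broadband background with a state-dependent oscillation —
  a delta-band (1-4 Hz) component under anaesthesia, a beta-band
  (12-30 Hz) component in wakefulness;
* mains interference at 50 or 60 Hz;
* a train of negative-going seizure-like events whose onset and
  cessation (minutes after drug application), amplitudes (mV) and
  inter-event intervals (s) are drawn from the published group
  statistics, with a gradual amplitude build-up at the start of the
  train;
* a spectral state change during the seizure span — the delta
  component is suppressed and a beta-band component appears — matching
  the reported drop in 1-4 Hz power and rise in 12-30 Hz power;
* an ENG channel carrying 1:1-coupled (configurable) compound action
  potentials at short latency after each LFP event.

All randomness flows from one seeded NumPy generator (PCG64), so a
given ``(config, seed)`` reproduces recordings and truth bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .core import ParameterError, Recording

__all__ = [
    "SynthConfig",
    "SynthGroundTruth",
    "preset",
    "PRESETS",
    "generate_background",
    "generate_event_train",
    "inject_events",
    "generate_eng",
    "generate_paired_recording",
]


@dataclass(frozen=True)
class SynthConfig:
    """All tunables of the simulator; see field comments for units."""

    duration_s: float = 3000.0
    fs_lfp: float = 10000.0
    fs_eng: float = 2000.0
    state: str = "anaesthetized"  # or "awake"
    application_time_s: float = 600.0
    events_enabled: bool = True
    # event-train statistics (minutes / mV / seconds)
    onset_min_mean: float = 10.31
    onset_min_sd: float = 5.1
    cessation_min_mean: float = 32.83
    cessation_min_sd: float = 12.38
    amp_mean_mv: float = 1.64
    amp_sd_mv: float = 0.67
    interval_mean_s: float = 1.01
    interval_sd_s: float = 0.88
    buildup_fraction: float = 0.15  # fraction of the train ramping 0.2 -> 1.0
    event_width_ms: float = 40.0
    # ENG coupling
    couple_prob: float = 1.0
    eng_latency_ms_mean: float = 20.0
    eng_latency_jitter_ms: float = 10.0
    eng_noise_sd_mv: float = 0.02
    eng_cap_amp_mv: float = 0.5
    # background / nuisance structure
    line_freq_hz: float = 60.0
    line_amp_mv: float = 0.05
    noise_sd_mv: float = 0.1
    osc_delta_rel: float = 1.0  # anaesthetized delta osc SD relative to pink SD
    osc_beta_rel: float = 0.7  # awake beta osc SD relative to pink SD
    seizure_delta_suppression: float = 0.3  # delta osc amplitude factor in seizure
    seizure_beta_rel: float = 0.7  # beta component added during seizure
    artifact_at_application: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "duration_s", "fs_lfp", "fs_eng", "amp_sd_mv", "interval_mean_s",
            "onset_min_sd", "cessation_min_sd", "interval_sd_s", "noise_sd_mv",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.couple_prob <= 1.0:
            raise ParameterError("couple_prob must be in [0, 1]")
        if self.state not in ("anaesthetized", "awake"):
            raise ParameterError(f"unknown state {self.state!r}")
        if self.events_enabled and self.onset_min_mean > self.cessation_min_mean:
            raise ParameterError("expected onset < cessation")


@dataclass(frozen=True)
class SynthGroundTruth:
    """The injected truth behind a simulated pair of recordings."""

    event_times_s: np.ndarray
    event_amps_mv: np.ndarray
    eng_cap_times_s: np.ndarray
    coupled_flags: np.ndarray
    onset_min: float | None = None
    cessation_min: float | None = None

    def __post_init__(self) -> None:
        if self.coupled_flags.size != self.event_times_s.size:
            raise ParameterError("one coupled flag per LFP event required")


# Presets encode the published group statistics per condition: amplitude
# 1.64 +/- 0.67 mV and interval 1.01 +/- 0.88 s under anaesthesia
# (1.4 +/- 0.82 mV, 0.83 +/- 0.75 s awake); onset 10.31 +/- 5.1 min and
# cessation 32.83 +/- 12.38 min at 100 uM versus 5.16 +/- 3.41 min and
# 47.50 +/- 19.41 min at 250 uM.
PRESETS: dict[str, SynthConfig] = {
    "anaesthetized_100uM": SynthConfig(
        state="anaesthetized",
        onset_min_mean=10.31, onset_min_sd=5.1,
        cessation_min_mean=32.83, cessation_min_sd=12.38,
        amp_mean_mv=1.64, amp_sd_mv=0.67,
        interval_mean_s=1.01, interval_sd_s=0.88,
        duration_s=3000.0,
    ),
    "anaesthetized_250uM": SynthConfig(
        state="anaesthetized",
        onset_min_mean=5.16, onset_min_sd=3.41,
        cessation_min_mean=47.50, cessation_min_sd=19.41,
        amp_mean_mv=1.64, amp_sd_mv=0.67,
        interval_mean_s=1.01, interval_sd_s=0.88,
        duration_s=4200.0,
    ),
    "awake_100uM": SynthConfig(
        state="awake",
        onset_min_mean=10.31, onset_min_sd=5.1,
        cessation_min_mean=32.83, cessation_min_sd=12.38,
        amp_mean_mv=1.4, amp_sd_mv=0.82,
        interval_mean_s=0.83, interval_sd_s=0.75,
        duration_s=3000.0,
    ),
    "control": SynthConfig(events_enabled=False, duration_s=1200.0),
}


def preset(name: str, **overrides) -> SynthConfig:
    """A named study condition, optionally with field overrides."""
    try:
        cfg = PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    return replace(cfg, **overrides) if overrides else cfg


def _truncnorm(rng, mean, sd, lo=0.0, hi=np.inf, size=None):
    if sd == 0:
        out = np.full(size, float(np.clip(mean, lo, hi))) if size else float(
            np.clip(mean, lo, hi)
        )
        return out
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sp_stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                                  random_state=rng)


def _pink_noise(rng, n: int, fs: float) -> np.ndarray:
    """Unit-SD 1/f-shaped noise, flattened below 0.5 Hz, rolled off above 100 Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    lo, hi = 0.5, 100.0
    band = f >= lo
    shape[band] = np.sqrt(lo / f[band])
    high = f > hi
    shape[high] *= hi / f[high]
    out = np.fft.irfft(spec * shape, n=n)
    sd = out.std()
    if sd > 0:
        out = out / sd
    # Bounded tails, as for the narrowband components: background alone
    # must not produce threshold-crossing excursions.
    out = 3.5 * np.tanh(out / 3.5)
    sd = out.std()
    return out / sd if sd > 0 else out


def _narrowband(rng, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-SD band-limited Gaussian noise.

    Ten seconds of padding on both sides are generated and trimmed so
    filter edge transients never reach the returned trace.
    """
    nyq = fs / 2.0
    lo = band[0] / nyq
    hi = min(band[1] / nyq, 0.99)
    pad = int(round(10.0 * fs))
    sos = sp_signal.butter(4, [lo, hi], btype="bandpass", output="sos")
    out = sp_signal.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))
    out = out[pad : pad + n]
    sd = out.std()
    if sd > 0:
        out = out / sd
    # Physiological oscillations have bounded amplitude, not Gaussian
    # tails: soft-saturate at 3 SD so rare slow excursions cannot mimic
    # threshold-crossing events.
    out = 3.0 * np.tanh(out / 3.0)
    sd = out.std()
    return out / sd if sd > 0 else out


def generate_background(cfg: SynthConfig, rng=None) -> np.ndarray:
    """Stationary background trace (mV) for the configured brain state.

    Pink noise plus the state oscillation, rescaled so the overall SD
    equals ``noise_sd_mv``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = int(round(cfg.duration_s * cfg.fs_lfp))
    pink = _pink_noise(rng, n, cfg.fs_lfp)
    if cfg.state == "anaesthetized":
        osc = cfg.osc_delta_rel * _narrowband(rng, n, cfg.fs_lfp, (1.0, 4.0))
        rel = cfg.osc_delta_rel
    else:
        osc = cfg.osc_beta_rel * _narrowband(rng, n, cfg.fs_lfp, (12.0, 30.0))
        rel = cfg.osc_beta_rel
    scale = cfg.noise_sd_mv / np.sqrt(1.0 + rel**2)
    return scale * (pink + osc)


def _moment_matched_lognormal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Log-normal gaps with the requested mean and SD (positive support)."""
    if sd == 0:
        return np.full(size, mean)
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def generate_event_train(
    cfg: SynthConfig, rng=None
) -> tuple[np.ndarray, np.ndarray, float | None, float | None]:
    """Event times (absolute s) and amplitudes (mV) for one recording.

    Onset and cessation (minutes after application) come from truncated
    normals; inter-event gaps from a moment-matched log-normal;
    amplitudes from a positive truncated normal, with the first
    ``buildup_fraction`` of the train ramped linearly from 20 % to 100 %
    to emulate the gradual amplitude build-up.  Events past the end of
    the recording are dropped.

    Returns ``(times, amps, onset_min, cessation_min)``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if not cfg.events_enabled or cfg.amp_mean_mv <= 0:
        return np.empty(0), np.empty(0), None, None
    onset = float(_truncnorm(rng, cfg.onset_min_mean, cfg.onset_min_sd, lo=0.0))
    cessation = None
    for _ in range(100):
        c = float(_truncnorm(rng, cfg.cessation_min_mean, cfg.cessation_min_sd, lo=0.0))
        if c > onset:
            cessation = c
            break
    if cessation is None:
        raise ParameterError(
            "could not draw a cessation later than the onset in 100 attempts"
        )
    t0 = cfg.application_time_s + onset * 60.0
    t_end = min(cfg.application_time_s + cessation * 60.0, cfg.duration_s - 1.0)
    if t0 >= t_end:
        return np.empty(0), np.empty(0), onset, cessation
    # draw gaps in bulk, then trim to the train span
    est_n = max(int((t_end - t0) / cfg.interval_mean_s * 2) + 10, 16)
    gaps = _moment_matched_lognormal(rng, cfg.interval_mean_s, cfg.interval_sd_s, est_n)
    times = t0 + np.concatenate([[0.0], np.cumsum(gaps)])
    times = times[times <= t_end]
    n = times.size
    amps = np.asarray(_truncnorm(rng, cfg.amp_mean_mv, cfg.amp_sd_mv, lo=0.0, size=n))
    n_ramp = int(np.ceil(cfg.buildup_fraction * n))
    if n_ramp > 0:
        amps[:n_ramp] *= np.linspace(0.2, 1.0, n_ramp)
    return times, amps, onset, cessation


def _event_kernel(fs: float, width_ms: float) -> tuple[np.ndarray, int]:
    """Unit-depth biphasic waveform; returns (kernel, index of the minimum)."""
    width = width_ms / 1000.0
    sigma_n = (width / 2.0) / 2.355  # FWHM of the negative lobe = width/2
    sigma_p = width / 2.355
    offset = width  # rebound peak trails the negative peak by one width
    t = np.arange(-3 * sigma_n, offset + 3 * sigma_p, 1.0 / fs)
    kernel = -np.exp(-0.5 * (t / sigma_n) ** 2) + 0.25 * np.exp(
        -0.5 * ((t - offset) / sigma_p) ** 2
    )
    kernel /= -kernel.min()  # depth exactly one unit of amplitude
    return kernel, int(np.argmin(kernel))


def inject_events(
    background: np.ndarray,
    times: np.ndarray,
    amps: np.ndarray,
    event_width_ms: float,
    fs: float,
) -> np.ndarray:
    """Add biphasic seizure-like transients to a background trace.

    Each event contributes a sharp negative lobe of depth ``amp`` and a
    25 % positive rebound; the negative peak lands at the stated time to
    within one sample.
    """
    out = np.array(background, dtype=np.float64, copy=True)
    if len(times) == 0:
        return out
    kernel, i_min = _event_kernel(fs, event_width_ms)
    for t, a in zip(times, amps):
        center = int(round(t * fs))
        start = center - i_min
        stop = start + kernel.size
        if center < 0 or center >= out.size:
            raise ParameterError(f"event at {t} s lies outside the trace")
        k0 = max(0, -start)
        k1 = kernel.size - max(0, stop - out.size)
        out[start + k0 : start + k1] += a * kernel[k0:k1]
    return out


def generate_eng(
    event_times: np.ndarray, cfg: SynthConfig, rng=None
) -> tuple[Recording, np.ndarray, np.ndarray]:
    """ENG channel with coupled compound action potentials.

    Each LFP event emits, with probability ``couple_prob``, a biphasic
    5 ms discharge at a truncated-normal latency within [0, 200] ms.

    Returns ``(recording, cap_times, coupled_flags)``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = int(round(cfg.duration_s * cfg.fs_eng))
    samples = rng.standard_normal(n) * cfg.eng_noise_sd_mv
    n_ev = len(event_times)
    coupled = (rng.random(n_ev) < cfg.couple_prob).astype(np.int8)
    latencies = np.asarray(
        _truncnorm(
            rng, cfg.eng_latency_ms_mean / 1000.0,
            cfg.eng_latency_jitter_ms / 1000.0, lo=0.0, hi=0.2,
            size=n_ev,
        )
    ) if n_ev else np.empty(0)
    cap_len = int(round(0.005 * cfg.fs_eng))
    tt = np.arange(cap_len) / cfg.fs_eng
    cap = np.sin(2 * np.pi * tt / 0.005) * np.hanning(cap_len) * cfg.eng_cap_amp_mv
    cap_times = []
    for t_ev, lat, flag in zip(event_times, latencies, coupled):
        if not flag:
            continue
        t_cap = t_ev + lat
        i0 = int(round(t_cap * cfg.fs_eng))
        if i0 + cap_len > n:
            continue
        samples[i0 : i0 + cap_len] += cap
        cap_times.append(t_cap)
    markers = {}
    if cfg.application_time_s <= cfg.duration_s:
        markers["application"] = cfg.application_time_s
    rec = Recording(samples=samples, fs=cfg.fs_eng, kind="ENG", markers=markers)
    return rec, np.asarray(cap_times), coupled


def _seizure_gate(n: int, fs: float, span: tuple[float, float] | None,
                  ramp_s: float = 5.0) -> np.ndarray:
    """0->1->0 gate over the seizure span with raised-cosine-like ramps."""
    if span is None:
        return np.zeros(n)
    t = np.arange(n) / fs
    s0, s1 = span
    return np.interp(t, [s0 - ramp_s, s0, s1, s1 + ramp_s], [0.0, 1.0, 1.0, 0.0])


def generate_paired_recording(
    cfg: SynthConfig,
) -> tuple[Recording, Recording, SynthGroundTruth]:
    """Full simulated experiment: LFP + ENG + ground truth.

    During the seizure span the anaesthetic delta oscillation is
    suppressed to ``seizure_delta_suppression`` of its amplitude and a
    beta-band component of relative SD ``seizure_beta_rel`` fades in,
    reproducing the reported spectral state change alongside the event
    train itself.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs_lfp))

    pink = _pink_noise(rng, n, cfg.fs_lfp)
    delta = _narrowband(rng, n, cfg.fs_lfp, (1.0, 4.0))
    beta = _narrowband(rng, n, cfg.fs_lfp, (12.0, 30.0))

    times, amps, onset, cessation = generate_event_train(cfg, rng)
    span = (float(times[0]), float(times[-1])) if times.size else None
    gate = _seizure_gate(n, cfg.fs_lfp, span)

    if cfg.state == "anaesthetized":
        rel = cfg.osc_delta_rel
        osc = rel * delta * (1.0 - (1.0 - cfg.seizure_delta_suppression) * gate)
    else:
        rel = cfg.osc_beta_rel
        osc = rel * beta
    seiz_beta = cfg.seizure_beta_rel * beta * gate if cfg.state == "anaesthetized" \
        else cfg.seizure_beta_rel * _narrowband(rng, n, cfg.fs_lfp, (12.0, 30.0)) * gate
    scale = cfg.noise_sd_mv / np.sqrt(1.0 + rel**2)
    background = scale * (pink + osc + seiz_beta)

    lfp_samples = inject_events(background, times, amps, cfg.event_width_ms,
                                cfg.fs_lfp)
    if cfg.line_amp_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / cfg.fs_lfp
        lfp_samples += cfg.line_amp_mv * np.sin(
            2 * np.pi * cfg.line_freq_hz * t + phase
        )
    if cfg.artifact_at_application:
        t = np.arange(n) / cfg.fs_lfp
        after = t >= cfg.application_time_s
        lfp_samples[after] += 3.0 * np.exp(
            -(t[after] - cfg.application_time_s) / 2.0
        )

    markers = {}
    if cfg.application_time_s <= cfg.duration_s:
        markers["application"] = cfg.application_time_s
        washout = cfg.application_time_s + 600.0
        if washout <= cfg.duration_s:
            markers["washout"] = washout
    lfp = Recording(samples=lfp_samples, fs=cfg.fs_lfp, kind="LFP", markers=markers)
    eng, cap_times, coupled = generate_eng(times, cfg, rng)
    truth = SynthGroundTruth(
        event_times_s=times,
        event_amps_mv=amps,
        eng_cap_times_s=cap_times,
        coupled_flags=coupled,
        onset_min=onset,
        cessation_min=cessation,
    )
    return lfp, eng, truth
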
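"""Preprocessing chain: line-noise removal, downsampling, z-scoring.

The intended order is ``remove_line_noise`` at the native rate, then
``resample_to`` the 1 kHz working rate, and ``zscore`` only on traces
destined for spectral analysis — event detection runs on the mV trace so
amplitudes stay in physical units.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .core import DegenerateSignalError, ParameterError, Recording

__all__ = ["remove_line_noise", "resample_to", "zscore"]


def _fit_line(segment: np.ndarray, fs: float, freq: float) -> np.ndarray:
    """Least-squares sinusoid at ``freq`` fitted over ``segment``.

    Returns the fitted waveform (same length).  Equivalent to projecting
    onto cos/sin regressors, which estimates amplitude and phase of a
    stationary line component.
    """
    t = np.arange(segment.size) / fs
    c = np.cos(2 * np.pi * freq * t)
    s = np.sin(2 * np.pi * freq * t)
    design = np.column_stack([c, s])
    coef, *_ = np.linalg.lstsq(design, segment, rcond=None)
    return design @ coef


def remove_line_noise(
    rec: Recording,
    freqs: tuple[float, ...] | set[float] = (50.0, 60.0),
    n_harmonics: int = 1,
    fit_window_s: float = 10.0,
) -> Recording:
    """Subtract mains interference by windowed sinusoid regression.

    For each target frequency (and its first ``n_harmonics`` multiples)
    the amplitude and phase are estimated by least squares over
    overlapping ``fit_window_s`` windows (50 % overlap) and the fitted
    sinusoid is subtracted, with triangular cross-fading between
    windows so slow drifts in line amplitude are tracked without edge
    discontinuities.  Subtraction is unconditional: when no line is
    present the fitted amplitude is ~0 and the trace is unchanged.
    """
    nyquist = rec.fs / 2
    targets = []
    for f in sorted(freqs):
        for h in range(1, n_harmonics + 1):
            if f * h >= nyquist:
                if h == 1:
                    raise ParameterError(
                        f"line frequency {f} Hz is at or above Nyquist ({nyquist} Hz)"
                    )
                break
            targets.append(f * h)
    x = rec.samples
    if x.size == 0 or not targets:
        return rec.with_samples(x.copy())

    win_n = min(int(round(fit_window_s * rec.fs)), x.size)
    win_n = max(win_n, 2)
    hop = max(win_n // 2, 1)
    fitted = np.zeros_like(x)
    weight = np.zeros_like(x)
    # Triangular weights overlap-add to a constant in the interior.
    tri = np.bartlett(win_n) + 1e-6
    start = 0
    while True:
        stop = min(start + win_n, x.size)
        seg = x[start:stop]
        w = tri[: seg.size]
        est = np.zeros_like(seg)
        for f in targets:
            est += _fit_line(seg - est, rec.fs, f)
        fitted[start:stop] += w * est
        weight[start:stop] += w
        if stop == x.size:
            break
        start += hop
    return rec.with_samples(x - fitted / weight)


def resample_to(rec: Recording, target_fs: float) -> Recording:
    """Downsample to ``target_fs`` with polyphase anti-alias filtering.

    Uses a Kaiser-windowed FIR low-pass inside :func:`scipy.signal.resample_poly`
    with reflect padding, so a sub-Nyquist sinusoid keeps its amplitude
    to within 1 % while content above the new Nyquist is strongly
    attenuated.  Upsampling is refused (the pipeline never needs it).
    """
    if target_fs > rec.fs:
        raise ParameterError(
            f"upsampling ({rec.fs} -> {target_fs} Hz) is not supported"
        )
    if target_fs == rec.fs:
        return rec.with_samples(rec.samples.copy())
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    y = signal.resample_poly(
        rec.samples, ratio.numerator, ratio.denominator,
        window=("kaiser", 8.0), padtype="line",
    )
    return rec.with_samples(y, fs=target_fs)


def zscore(rec: Recording) -> Recording:
    """Normalize a trace to zero mean, unit SD over the entire recording.

    The population SD (divide by n) is used; at recording lengths of
    minutes the difference from the sample SD is negligible.  The output
    is dimensionless; markers are preserved.
    """
    x = rec.samples
    if x.size == 0:
        raise ParameterError("cannot z-score an empty recording")
    sd = float(np.std(x))
    if sd == 0:
        raise DegenerateSignalError("constant trace cannot be z-scored")
    return rec.with_samples((x - np.mean(x)) / sd)
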
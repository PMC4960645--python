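"""Multitaper spectral estimation (DPSS), spectrograms and band power.

Estimation follows the classic Thomson recipe: K orthonormal Slepian
tapers at time-bandwidth product NW, the one-sided power spectral
density averaged over tapers with equal weights.  Defaults are NW = 3,
K = 5 tapers, no zero-padding (a "padding factor" of -1 means the FFT
length equals the segment length), 2.5 s windows sliding by 50 ms for
spectrograms.  Power is in units of (input units)^2 / Hz; dB values are
10*log10 of linear power with a configurable floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import windows

from .core import ParameterError, Recording

__all__ = [
    "SpectralEstimate",
    "Spectrogram",
    "BandPowerChange",
    "dpss_tapers",
    "multitaper_spectrum",
    "multitaper_spectrogram",
    "smooth_spectrum",
    "band_power",
    "band_power_change",
]

#: Linear power below this is clamped before taking logs (keeps dB finite
#: for silent signals without affecting any physical power level).
DB_FLOOR = 1e-12


def db(power: np.ndarray | float, floor: float = DB_FLOOR) -> np.ndarray:
    """Convert linear power to decibels with a floor at ``floor``."""
    return 10.0 * np.log10(np.maximum(power, floor))


@dataclass(frozen=True)
class SpectralEstimate:
    """One-sided multitaper PSD on a uniform frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        if self.freqs.shape != self.power.shape:
            raise ParameterError("freqs and power must have equal length")
        if np.any(self.power < 0):
            raise ParameterError("power must be non-negative")

    @property
    def power_db(self) -> np.ndarray:
        return db(self.power)


@dataclass(frozen=True)
class Spectrogram:
    """Sliding-window multitaper power: time x frequency matrix."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        if self.power.shape != (self.times.size, self.freqs.size):
            raise ParameterError("power must be (n_times, n_freqs)")

    @property
    def power_db(self) -> np.ndarray:
        return db(self.power)


@dataclass(frozen=True)
class BandPowerChange:
    """Mean band power in two periods and their ratio in % of baseline."""

    band: tuple[float, float]
    p1_db: float
    p2_db: float

    @property
    def pct_of_baseline(self) -> float:
        return 100.0 * 10.0 ** ((self.p2_db - self.p1_db) / 10.0)


def dpss_tapers(n: int, nw: float = 3.0, k: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Discrete prolate spheroidal (Slepian) tapers and concentrations.

    Returns a (k, n) matrix of unit-norm orthonormal tapers and their
    in-band energy concentrations, sorted descending.
    """
    if not 1 <= k:
        raise ParameterError("k must be >= 1")
    if k > 2 * nw - 1:
        raise ParameterError(f"k={k} exceeds 2*nw-1={2 * nw - 1}")
    if n < k:
        raise ParameterError(f"need n >= k tapers, got n={n}, k={k}")
    tapers, ratios = windows.dpss(n, nw, Kmax=k, return_ratios=True, norm=2)
    return np.atleast_2d(tapers), np.atleast_1d(ratios)


def _nfft_for(n: int, padding: int) -> int:
    if padding < 0:
        return n
    return int(2 ** (np.ceil(np.log2(n)) + padding))


def multitaper_spectrum(
    segment: np.ndarray,
    fs: float,
    nw: float = 3.0,
    k: int = 5,
    padding: int = -1,
    tapers: np.ndarray | None = None,
) -> SpectralEstimate:
    """One-sided multitaper PSD of a single segment.

    ``power[f] = (2/fs) * mean_k |FFT(taper_k * x)[f]|^2`` for interior
    frequencies (DC and Nyquist keep the one-sided factor of 1), with
    unit-norm tapers so that ``sum(power) * df`` estimates the segment
    variance.  ``padding=-1`` means no zero-padding; ``padding >= 0``
    pads to ``2**(nextpow2(n) + padding)``.

    ``tapers`` overrides the DPSS family (used e.g. to force a single
    rectangular taper, which reduces the estimate to the periodogram).
    """
    x = np.asarray(segment, dtype=np.float64)
    if x.ndim != 1:
        raise ParameterError("segment must be one-dimensional")
    if tapers is None:
        if x.size < 2 * k:
            raise ParameterError(
                f"segment of {x.size} samples too short for k={k} tapers"
            )
        tapers, _ = dpss_tapers(x.size, nw, k)
    else:
        tapers = np.atleast_2d(np.asarray(tapers, dtype=np.float64))
        if tapers.shape[1] != x.size:
            raise ParameterError("taper length must match segment length")
    nfft = _nfft_for(x.size, padding)
    spectra = np.fft.rfft(tapers * x[None, :], n=nfft, axis=1)
    psd = (np.abs(spectra) ** 2).mean(axis=0) / fs
    # one-sided correction: double everything except DC (and Nyquist if present)
    psd[1:] *= 2.0
    if nfft % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    params = {
        "nw": nw,
        "k_tapers": int(tapers.shape[0]),
        "n_samples": int(x.size),
        "fs": fs,
        "padding": padding,
        "nfft": nfft,
    }
    return SpectralEstimate(freqs=freqs, power=psd, params=params)


def multitaper_spectrogram(
    rec: Recording,
    window_s: float = 2.5,
    step_s: float = 0.05,
    nw: float = 3.0,
    k: int = 5,
    padding: int = -1,
) -> Spectrogram:
    """Sliding-window multitaper spectrogram.

    Windows start at the beginning of the recording and advance by
    ``step_s``; only full windows are evaluated, so the number of time
    slices is ``floor((duration - window_s)/step_s) + 1``.  Times are
    window centers.
    """
    if rec.duration < window_s:
        raise ParameterError(
            f"recording of {rec.duration:.3f} s shorter than window {window_s} s"
        )
    win_n = int(round(window_s * rec.fs))
    step_n = max(int(round(step_s * rec.fs)), 1)
    tapers, _ = dpss_tapers(win_n, nw, k)
    starts = np.arange(0, rec.n - win_n + 1, step_n)
    nfft = _nfft_for(win_n, padding)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rec.fs)
    power = np.empty((starts.size, freqs.size))
    for i, s0 in enumerate(starts):
        est = multitaper_spectrum(
            rec.samples[s0 : s0 + win_n], rec.fs, nw=nw, k=k,
            padding=padding, tapers=tapers,
        )
        power[i] = est.power
    times = rec.start_time + (starts + win_n / 2) / rec.fs
    params = {"window_s": window_s, "step_s": step_s, "nw": nw, "k_tapers": k}
    return Spectrogram(times=times, freqs=freqs, power=power, params=params)


def smooth_spectrum(
    spec: SpectralEstimate, window_bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving average and moving SD of the power over frequency.

    Edge bins use truncated windows.  Returns ``(smoothed, sd_envelope)``
    in linear power units on the same frequency grid.
    """
    if window_bins < 1:
        raise ParameterError("window_bins must be >= 1")
    if window_bins > spec.power.size:
        raise ParameterError(
            f"window_bins={window_bins} exceeds the {spec.power.size} bins available"
        )
    s = pd.Series(spec.power)
    rolling = s.rolling(window_bins, center=True, min_periods=1)
    smoothed = rolling.mean().to_numpy()
    sd = rolling.std(ddof=1).fillna(0.0).to_numpy()
    return smoothed, sd


def band_power(spec: SpectralEstimate | Spectrogram, band: tuple[float, float]) -> float:
    """Mean power in dB over grid frequencies inside ``band`` (ends inclusive).

    For a spectrogram the mean is taken over all time slices as well.
    """
    lo, hi = band
    if not lo < hi:
        raise ParameterError(f"band ({lo}, {hi}) must have lo < hi")
    sel = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not np.any(sel):
        raise ParameterError(f"no grid frequencies inside band ({lo}, {hi}) Hz")
    if isinstance(spec, Spectrogram):
        return float(np.mean(spec.power_db[:, sel]))
    return float(np.mean(spec.power_db[sel]))


def band_power_change(
    rec: Recording,
    period1: tuple[float, float],
    period2: tuple[float, float],
    band: tuple[float, float],
    nw: float = 3.0,
    k: int = 5,
    min_period_s: float = 2.5,
) -> BandPowerChange:
    """Relative band-power change of period 2 versus period 1.

    Both periods (seconds from recording start) get a multitaper PSD of
    the full period; the change is ``100 * 10**((p2_db - p1_db)/10)`` %
    of baseline.  ``rec`` should already be the z-scored working trace.
    """
    for name, (t0, t1) in (("period1", period1), ("period2", period2)):
        if not (0 <= t0 < t1 <= rec.duration + 0.5 / rec.fs):
            raise ParameterError(f"{name}=({t0}, {t1}) outside recording")
        if t1 - t0 < min_period_s:
            raise ParameterError(f"{name} shorter than {min_period_s} s")
    if period1 != period2 and (
        max(period1[0], period2[0]) < min(period1[1], period2[1])
    ):
        raise ParameterError("periods must not overlap")
    p_db = []
    for t0, t1 in (period1, period2):
        est = multitaper_spectrum(rec.segment(t0, t1), rec.fs, nw=nw, k=k)
        p_db.append(band_power(est, band))
    return BandPowerChange(band=band, p1_db=p_db[0], p2_db=p_db[1])


def band_power_changes(
    rec: Recording,
    period1: tuple[float, float],
    period2: tuple[float, float],
    bands: dict[str, tuple[float, float]],
    nw: float = 3.0,
    k: int = 5,
) -> dict[str, BandPowerChange]:
    """Band-power change for several bands off one spectrum per period."""
    ests = [
        multitaper_spectrum(rec.segment(t0, t1), rec.fs, nw=nw, k=k)
        for t0, t1 in (period1, period2)
    ]
    return {
        name: BandPowerChange(
            band=band,
            p1_db=band_power(ests[0], band),
            p2_db=band_power(ests[1], band),
        )
        for name, band in bands.items()
    }
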
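"""Shared domain types for the LFP/ENG seizure-analysis pipeline.

Conventions used throughout the package:

* time is in seconds from recording start (sample ``i`` of a
  :class:`Recording` sits at ``start_time + i / fs``);
* voltages are in millivolts unless a trace has been z-scored, in which
  case it is dimensionless;
* event amplitudes are positive magnitudes of the negative deflection,
  measured from the baseline mean to the negative peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "SeizlfpError",
    "ParameterError",
    "ParseError",
    "SamplingError",
    "DegenerateSignalError",
    "UndefinedCorrelationError",
    "Recording",
    "BaselineStats",
    "EventSet",
    "EventSummary",
    "AnalysisConfig",
]


class SeizlfpError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(SeizlfpError, ValueError):
    """An argument violates an operation's precondition."""


class ParseError(SeizlfpError, ValueError):
    """A file does not conform to the expected dialect."""


class SamplingError(SeizlfpError, ValueError):
    """A time column is non-uniform or otherwise unusable."""


class DegenerateSignalError(SeizlfpError, ValueError):
    """A signal has no variance where variance is required."""


class UndefinedCorrelationError(SeizlfpError, ValueError):
    """A correlation is requested on data with zero variance."""


@dataclass
class Recording:
    """A uniformly sampled single-channel voltage trace.

    Parameters
    ----------
    samples
        Voltage samples in mV (dimensionless after z-scoring).
    fs
        Sampling rate in Hz, strictly positive.
    kind
        Channel kind, ``"LFP"`` or ``"ENG"``.
    start_time
        Time of the first sample in seconds (default 0).
    markers
        Named time points in seconds, e.g. ``{"application": 600.0}``.
        Markers must fall inside the recorded interval.
    """

    samples: np.ndarray
    fs: float
    kind: str = "LFP"
    start_time: float = 0.0
    markers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ParameterError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples must all be finite")
        if not (self.fs > 0 and math.isfinite(self.fs)):
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if self.kind not in ("LFP", "ENG"):
            raise ParameterError(f"kind must be 'LFP' or 'ENG', got {self.kind!r}")
        end = self.start_time + self.n / self.fs
        for name, t in self.markers.items():
            if not (self.start_time <= t <= end):
                raise ParameterError(
                    f"marker {name!r} at {t} s lies outside "
                    f"[{self.start_time}, {end}] s"
                )

    @property
    def n(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration(self) -> float:
        """Recording length in seconds (``n / fs``)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "Recording":
        """Copy of this recording with new samples (and optionally a new rate)."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64),
                       fs=self.fs if fs is None else fs,
                       markers=dict(self.markers))

    def segment(self, t0: float, t1: float) -> np.ndarray:
        """Samples in ``[t0, t1)``, times relative to recording start."""
        if not (0.0 <= t0 < t1 <= self.duration + 0.5 / self.fs):
            raise ParameterError(f"segment [{t0}, {t1}] outside recording")
        i0 = int(round(t0 * self.fs))
        i1 = int(round(t1 * self.fs))
        return self.samples[i0:i1]


@dataclass(frozen=True)
class BaselineStats:
    """Mean and SD of a trace over a baseline window (default: first 5 min)."""

    mean: float
    sd: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ParameterError("baseline sd must be >= 0")
        if not self.window[1] > self.window[0]:
            raise ParameterError("baseline window must have positive length")


@dataclass(frozen=True)
class EventSet:
    """Detected seizure-like events with the statistics that produced them.

    ``times`` hold the time of peak negativity of each event;
    ``amplitudes`` the baseline-mean-to-peak magnitude in mV.
    """

    times: np.ndarray
    amplitudes: np.ndarray
    threshold: float
    baseline: BaselineStats
    source_duration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=np.float64))
        object.__setattr__(
            self, "amplitudes", np.asarray(self.amplitudes, dtype=np.float64)
        )
        if self.times.shape != self.amplitudes.shape:
            raise ParameterError("times and amplitudes must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ParameterError("event times must be strictly increasing")
        margin = abs(self.threshold - self.baseline.mean)
        if self.amplitudes.size and np.any(self.amplitudes < margin - 1e-12):
            raise ParameterError("every amplitude must reach the threshold margin")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class EventSummary:
    """Per-recording event statistics (sample SDs, n-1 denominator).

    Onset and cessation are minutes from the application marker to the
    first and last event; ``None`` when not computable.
    """

    n_events: int
    amp_mean: float | None = None
    amp_sd: float | None = None
    interval_mean: float | None = None
    interval_sd: float | None = None
    onset: float | None = None
    cessation: float | None = None

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ParameterError("n_events must be >= 0")
        if self.onset is not None and self.cessation is not None:
            if self.onset > self.cessation + 1e-12:
                raise ParameterError("onset must not exceed cessation")


_DEFAULT_BANDS: Mapping[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "beta": (12.0, 30.0),
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Every tunable of the analysis chain, with the study's defaults.

    The defaults encode the published analysis: 5-min baseline, 4-SD
    negative threshold, 1 kHz working rate, multitaper NW=3 with 5
    tapers, 2.5 s windows sliding by 50 ms, 50-bin spectral smoothing,
    delta (1-4 Hz) and beta (12-30 Hz) bands, and 40-bin histograms.
    """

    baseline_window_s: float = 300.0
    threshold_k: float = 4.0
    min_event_duration_ms: float = 5.0
    merge_window_ms: float = 100.0
    line_freqs_hz: tuple[float, ...] = (50.0, 60.0)
    target_fs_hz: float = 1000.0
    nw: float = 3.0
    k_tapers: int = 5
    window_s: float = 2.5
    step_s: float = 0.05
    smooth_bins: int = 50
    bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BANDS)
    )
    eng_window_ms: float = 100.0
    histogram_bins: int = 40

    def __post_init__(self) -> None:
        positive = {
            "baseline_window_s": self.baseline_window_s,
            "threshold_k": self.threshold_k,
            "min_event_duration_ms": self.min_event_duration_ms,
            "merge_window_ms": self.merge_window_ms,
            "target_fs_hz": self.target_fs_hz,
            "nw": self.nw,
            "k_tapers": self.k_tapers,
            "window_s": self.window_s,
            "step_s": self.step_s,
            "smooth_bins": self.smooth_bins,
            "eng_window_ms": self.eng_window_ms,
            "histogram_bins": self.histogram_bins,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ParameterError(f"{name} must be positive, got {value}")
        if self.k_tapers > 2 * self.nw - 1:
            raise ParameterError(
                f"k_tapers={self.k_tapers} exceeds 2*nw-1={2 * self.nw - 1}"
            )
        for name, (lo, hi) in self.bands.items():
            if not (0 <= lo < hi < self.target_fs_hz / 2):
                raise ParameterError(
                    f"band {name!r}=({lo}, {hi}) must satisfy "
                    f"lo < hi < target_fs/2"
                )

    def to_dict(self) -> dict:
        return {
            "baseline_window_s": self.baseline_window_s,
            "threshold_k": self.threshold_k,
            "min_event_duration_ms": self.min_event_duration_ms,
            "merge_window_ms": self.merge_window_ms,
            "line_freqs_hz": list(self.line_freqs_hz),
            "target_fs_hz": self.target_fs_hz,
            "nw": self.nw,
            "k_tapers": self.k_tapers,
            "window_s": self.window_s,
            "step_s": self.step_s,
            "smooth_bins": self.smooth_bins,
            "bands": {k: list(v) for k, v in self.bands.items()},
            "eng_window_ms": self.eng_window_ms,
            "histogram_bins": self.histogram_bins,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        if "line_freqs_hz" in d:
            d["line_freqs_hz"] = tuple(d["line_freqs_hz"])
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        return cls(**d)
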
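"""Baseline-referenced detection of seizure-like LFP events.

The detector mirrors the published rule: the threshold sits 4 baseline
standard deviations more negative than the baseline mean (baseline =
first 5 minutes of the recording), an event is a supra-threshold
negative excursion, its time is the peak of negativity and its
amplitude the baseline-mean-to-peak magnitude in mV.  Two practical
guards — a minimum duration (5 ms) and a merge window (100 ms) — keep
single-sample noise from triggering and multi-lobed discharges from
double-counting; both are configuration-exposed.
"""

from __future__ import annotations

import numpy as np

from .core import (
    BaselineStats,
    DegenerateSignalError,
    EventSet,
    EventSummary,
    ParameterError,
    Recording,
)

__all__ = [
    "baseline_stats",
    "detect_events",
    "event_intervals",
    "summarize",
    "onset_cessation",
    "histogram",
    "HistogramResult",
]


def baseline_stats(rec: Recording, window_s: float = 300.0) -> BaselineStats:
    """Mean and SD of the trace over the first ``window_s`` seconds."""
    if rec.duration + 0.5 / rec.fs < window_s:
        raise ParameterError(
            f"recording of {rec.duration:.1f} s shorter than baseline "
            f"window of {window_s:.1f} s"
        )
    seg = rec.samples[: int(round(window_s * rec.fs))]
    return BaselineStats(
        mean=float(np.mean(seg)), sd=float(np.std(seg)), window=(0.0, window_s)
    )


def _runs_below(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True in a boolean mask."""
    if not mask.any():
        return []
    m = mask.astype(np.int8)
    d = np.diff(m)
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.concatenate([[0], starts])
    if m[-1]:
        stops = np.concatenate([stops, [m.size]])
    return list(zip(starts.tolist(), stops.tolist()))


def detect_events(
    rec: Recording,
    baseline: BaselineStats,
    k: float = 4.0,
    min_duration_ms: float = 5.0,
    merge_window_ms: float = 100.0,
) -> EventSet:
    """Detect negative-going events crossing ``mean - k*sd``.

    A candidate event is a maximal contiguous run of samples below the
    threshold lasting at least ``min_duration_ms``; candidates separated
    by gaps shorter than ``merge_window_ms`` merge into a single event.
    Event time = time of the most negative sample, amplitude =
    ``baseline.mean - min(sample)`` (a positive magnitude in mV).
    """
    if baseline.sd <= 0:
        raise DegenerateSignalError("baseline SD is zero; threshold undefined")
    threshold = baseline.mean - k * baseline.sd
    mask = rec.samples < threshold
    min_n = max(int(round(min_duration_ms / 1000.0 * rec.fs)), 1)
    runs = [r for r in _runs_below(mask) if r[1] - r[0] >= min_n]

    merge_n = int(round(merge_window_ms / 1000.0 * rec.fs))
    merged: list[tuple[int, int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < merge_n:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    times = np.empty(len(merged))
    amps = np.empty(len(merged))
    for i, (a, b) in enumerate(merged):
        span = rec.samples[a:b]
        j = int(np.argmin(span))
        times[i] = rec.start_time + (a + j) / rec.fs
        amps[i] = baseline.mean - span[j]
    return EventSet(
        times=times,
        amplitudes=amps,
        threshold=threshold,
        baseline=baseline,
        source_duration=rec.duration,
    )


def event_intervals(ev: EventSet) -> np.ndarray:
    """Successive inter-event intervals in seconds (empty if < 2 events)."""
    if len(ev) < 2:
        return np.empty(0)
    return np.diff(ev.times)


def summarize(ev: EventSet, application_time: float | None = None) -> EventSummary:
    """Amplitude/interval statistics plus onset and cessation in minutes.

    SDs use the n-1 denominator.  Onset/cessation are reported only when
    both an application time and at least one event exist.
    """
    n = len(ev)
    amp_mean = amp_sd = interval_mean = interval_sd = None
    onset = cessation = None
    if n >= 1:
        amp_mean = float(np.mean(ev.amplitudes))
        amp_sd = float(np.std(ev.amplitudes, ddof=1)) if n >= 2 else None
        if application_time is not None:
            onset = (float(ev.times[0]) - application_time) / 60.0
            cessation = (float(ev.times[-1]) - application_time) / 60.0
    if n >= 2:
        iv = event_intervals(ev)
        interval_mean = float(np.mean(iv))
        interval_sd = float(np.std(iv, ddof=1)) if iv.size >= 2 else None
    return EventSummary(
        n_events=n,
        amp_mean=amp_mean,
        amp_sd=amp_sd,
        interval_mean=interval_mean,
        interval_sd=interval_sd,
        onset=onset,
        cessation=cessation,
    )


def onset_cessation(
    ev: EventSet, application_time: float
) -> tuple[float, float, bool]:
    """Minutes from application to the first and last event.

    Returns ``(onset_min, cessation_min, warned)`` where ``warned`` is
    True when the first event precedes the application marker (negative
    onset is still returned).
    """
    if len(ev) == 0:
        raise ParameterError("no events; onset/cessation undefined")
    onset = (float(ev.times[0]) - application_time) / 60.0
    cessation = (float(ev.times[-1]) - application_time) / 60.0
    return onset, cessation, onset < 0


class HistogramResult:
    """Uniform-bin histogram: ``edges`` (bins+1) and ``counts`` (bins)."""

    __slots__ = ("edges", "counts")

    def __init__(self, edges: np.ndarray, counts: np.ndarray):
        self.edges = np.asarray(edges, dtype=np.float64)
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.edges.size != self.counts.size + 1:
            raise ParameterError("edges must have len(counts) + 1 entries")


def histogram(values, bins: int = 40) -> HistogramResult:
    """Histogram with uniform bins spanning [min, max], last bin inclusive.

    Degenerate input (all values identical) falls back to a single-value
    range of unit width so every value lands in one bin.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ParameterError("cannot histogram an empty sequence")
    if bins < 1:
        raise ParameterError("bins must be >= 1")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    return HistogramResult(edges=edges, counts=counts)
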
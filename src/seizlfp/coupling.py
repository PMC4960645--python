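"""LFP-to-ENG event coupling.

Each detected seizure-like LFP event opens a time window (default
±100 ms, truncated at midpoints when events crowd together).  The ENG
trace is screened inside each window for compound action potentials —
samples deviating from the ENG baseline mean by more than 4 baseline
SDs in either direction, persisting for at least 2 samples.  The window
is assigned 1 if a discharge is present and 0 otherwise; the cumulative
LFP count is then regressed against the cumulative ENG count and the
Pearson r² reported, together with the matched fraction (the r² of
cumulative counts can stay near 1 under partial coupling, so the
fraction is the sharper 1:1 statistic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    DegenerateSignalError,
    EventSet,
    ParameterError,
    Recording,
    UndefinedCorrelationError,
)
from .events import baseline_stats
from .stats import pearson

__all__ = [
    "CouplingResult",
    "binarize_lfp",
    "detect_caps_in_windows",
    "cumulative_match",
    "couple",
]


@dataclass(frozen=True)
class CouplingResult:
    """Per-event LFP/ENG binaries, cumulative counts, and their correlation."""

    lfp_event_times: np.ndarray
    lfp_binary: np.ndarray
    eng_binary: np.ndarray
    cum_lfp: np.ndarray
    cum_eng: np.ndarray
    r: float
    p: float

    @property
    def r_squared(self) -> float:
        return self.r**2

    @property
    def match_fraction(self) -> float:
        return float(np.mean(self.eng_binary))


def binarize_lfp(ev: EventSet, window_ms: float = 100.0) -> list[tuple[float, float]]:
    """One window ``[t - w, t + w]`` per event, truncated to stay disjoint.

    When neighbouring windows would overlap, both are cut at the
    midpoint between the two event times.
    """
    w = window_ms / 1000.0
    times = ev.times
    windows: list[tuple[float, float]] = []
    for i, t in enumerate(times):
        lo, hi = t - w, t + w
        if i > 0:
            lo = max(lo, (times[i - 1] + t) / 2.0)
        if i + 1 < times.size:
            hi = min(hi, (t + times[i + 1]) / 2.0)
        windows.append((float(lo), float(hi)))
    return windows


def detect_caps_in_windows(
    eng: Recording,
    windows: list[tuple[float, float]],
    k: float = 4.0,
    baseline_window_s: float = 300.0,
    persistence: int = 2,
) -> np.ndarray:
    """Screen ENG windows for compound action potentials.

    A window scores 1 when at least ``persistence`` consecutive samples
    satisfy ``|x - baseline.mean| > k * baseline.sd`` — two-sided,
    because compound action potentials are biphasic.
    """
    base = baseline_stats(eng, baseline_window_s)
    if base.sd <= 0:
        raise DegenerateSignalError("ENG baseline SD is zero")
    dev = np.abs(eng.samples - base.mean) > k * base.sd
    out = np.zeros(len(windows), dtype=np.int8)
    for i, (lo, hi) in enumerate(windows):
        i0 = max(int(np.floor((lo - eng.start_time) * eng.fs)), 0)
        i1 = min(int(np.ceil((hi - eng.start_time) * eng.fs)) + 1, eng.n)
        seg = dev[i0:i1]
        if seg.size >= persistence and _has_run(seg, persistence):
            out[i] = 1
    return out


def _has_run(mask: np.ndarray, length: int) -> bool:
    if length <= 1:
        return bool(mask.any())
    conv = np.convolve(mask.astype(np.int32), np.ones(length, dtype=np.int32), "valid")
    return bool((conv >= length).any())


def cumulative_match(
    eng_binary: np.ndarray, lfp_event_times: np.ndarray | None = None
) -> CouplingResult:
    """Correlate cumulative LFP event counts with cumulative ENG counts."""
    eng_binary = np.asarray(eng_binary, dtype=np.int8)
    n = eng_binary.size
    if n < 3:
        raise ParameterError("need at least 3 windows for a correlation")
    cum_lfp = np.arange(1, n + 1, dtype=np.float64)
    cum_eng = np.cumsum(eng_binary).astype(np.float64)
    if cum_eng[-1] == 0:
        raise UndefinedCorrelationError(
            "no ENG events detected; cumulative ENG count has zero variance"
        )
    res = pearson(cum_lfp, cum_eng)
    if lfp_event_times is None:
        lfp_event_times = np.arange(n, dtype=np.float64)
    return CouplingResult(
        lfp_event_times=np.asarray(lfp_event_times, dtype=np.float64),
        lfp_binary=np.ones(n, dtype=np.int8),
        eng_binary=eng_binary,
        cum_lfp=cum_lfp,
        cum_eng=cum_eng,
        r=float(res.statistic),
        p=float(res.p),
    )


def couple(
    ev: EventSet,
    eng: Recording,
    window_ms: float = 100.0,
    k: float = 4.0,
    baseline_window_s: float = 300.0,
) -> CouplingResult:
    """Full coupling chain: windows -> CAP screening -> cumulative r²."""
    windows = binarize_lfp(ev, window_ms)
    eng_binary = detect_caps_in_windows(eng, windows, k, baseline_window_s)
    return cumulative_match(eng_binary, lfp_event_times=ev.times)
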
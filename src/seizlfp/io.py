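"""Readers and writers for recordings and event tables.

Two recording formats are supported:

* ``columnar-text`` — CSV with a ``t_s,mv`` header row and ``#``-prefixed
  metadata lines (``fs_hz``, ``kind``, ``start_time_s``, ``marker <name>``).
  Values carry at least six significant digits.
* ``binary-container`` — a small documented binary layout (see
  :data:`MAGIC`): magic, version, fs, start time, kind, markers, then
  float64 little-endian samples.  Lossless round trip.

EDF input is not parsed here; convert externally to one of the above.
Event tables are TSV with commented threshold/baseline metadata.
"""

from __future__ import annotations

import io as _io
import struct
from pathlib import Path

import numpy as np

from .core import (
    BaselineStats,
    EventSet,
    ParameterError,
    ParseError,
    Recording,
    SamplingError,
)

__all__ = ["read_recording", "write_recording", "write_events", "read_events"]

#: Binary container layout, version 1 (all little-endian):
#:   8s   magic  b"SEIZLFP\x00"
#:   <I   version (1)
#:   <d   fs_hz
#:   <d   start_time_s
#:   4s   kind, NUL-padded ASCII ("LFP" / "ENG")
#:   <Q   n_samples
#:   <I   n_markers, then per marker: <H key_len, key UTF-8, <d time_s
#:   n_samples float64 samples
MAGIC = b"SEIZLFP\x00"
_VERSION = 1

FORMATS = ("columnar-text", "binary-container", "edf")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".csv", ".txt"):
        return "columnar-text"
    if suffix == ".edf":
        return "edf"
    return "binary-container"


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a :class:`~seizlfp.core.Recording` from disk.

    The sampling rate of text files is inferred from the time column and
    cross-checked against a ``# fs_hz=`` header when present; a jittery
    time column (deviations above 1 % of the sample period) raises
    :class:`~seizlfp.core.SamplingError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "columnar-text":
        return _read_text(path)
    if fmt == "binary-container":
        return _read_binary(path)
    if fmt == "edf":
        raise ParameterError(
            "EDF input is not supported by this build; convert the file to "
            "the columnar-text or binary-container format first"
        )
    raise ParameterError(f"unknown format {fmt!r}; expected one of {FORMATS}")


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write ``rec`` to ``path``; see module docstring for the dialects."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if not np.all(np.isfinite(rec.samples)):  # guards arrays mutated post-construction
        raise ParameterError("recording contains non-finite samples")
    if fmt == "columnar-text":
        _write_text(rec, path)
    elif fmt == "binary-container":
        _write_binary(rec, path)
    else:
        raise ParameterError(f"cannot write format {fmt!r}")
    return path


def _parse_meta(lines: list[str]) -> dict:
    meta: dict = {"markers": {}}
    for line in lines:
        body = line.lstrip("#").strip()
        if not body or "=" not in body:
            continue
        key, _, value = body.partition("=")
        key = key.strip()
        value = value.strip()
        try:
            if key == "fs_hz":
                meta["fs"] = float(value)
            elif key == "kind":
                meta["kind"] = value
            elif key == "start_time_s":
                meta["start_time"] = float(value)
            elif key.startswith("marker "):
                meta["markers"][key.split(None, 1)[1]] = float(value)
        except ValueError as exc:
            raise ParseError(f"bad metadata line {line!r}: {exc}") from exc
    return meta


def _read_text(path: Path) -> Recording:
    header_lines: list[str] = []
    data_lines: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header_lines.append(line)
            else:
                data_lines.append(line)
    if not data_lines:
        raise ParseError(f"{path}: no header row found")
    columns = [c.strip() for c in data_lines[0].split(",")]
    if columns[:2] != ["t_s", "mv"]:
        raise ParseError(f"{path}: expected header 't_s,mv', got {data_lines[0]!r}")
    meta = _parse_meta(header_lines)
    if len(data_lines) == 1:
        samples = np.empty(0)
        t = np.empty(0)
    else:
        try:
            arr = np.loadtxt(
                _io.StringIO("\n".join(data_lines[1:])), delimiter=",", ndmin=2
            )
        except ValueError as exc:
            raise ParseError(f"{path}: malformed data row: {exc}") from exc
        if arr.shape[1] != 2:
            raise ParseError(f"{path}: expected 2 columns, got {arr.shape[1]}")
        t, samples = arr[:, 0], arr[:, 1]

    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise SamplingError(f"{path}: time column is not strictly increasing")
        period = float(np.median(dt))
        if np.max(np.abs(dt - period)) > 0.01 * period:
            raise SamplingError(
                f"{path}: non-uniform time column (jitter exceeds 1% of the "
                f"sample period {period:g} s)"
            )
        fs = meta.get("fs", 1.0 / period)
        if abs(1.0 / period - fs) > 0.01 * fs:
            raise SamplingError(
                f"{path}: time column implies fs={1.0 / period:g} Hz but "
                f"header says {fs:g} Hz"
            )
        start_time = meta.get("start_time", float(t[0]))
    else:
        fs = meta.get("fs")
        if fs is None:
            raise ParseError(f"{path}: cannot infer fs from fewer than 2 samples")
        start_time = meta.get("start_time", float(t[0]) if t.size else 0.0)
    return Recording(
        samples=samples,
        fs=float(fs),
        kind=meta.get("kind", "LFP"),
        start_time=start_time,
        markers=meta["markers"],
    )


def _write_text(rec: Recording, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# seizlfp recording v1\n")
        fh.write(f"# fs_hz={rec.fs!r}\n")
        fh.write(f"# kind={rec.kind}\n")
        fh.write(f"# start_time_s={rec.start_time!r}\n")
        for name, t in sorted(rec.markers.items()):
            fh.write(f"# marker {name}={t!r}\n")
        fh.write("t_s,mv\n")
        times = rec.times
        for t, v in zip(times, rec.samples):
            fh.write(f"{t:.9g},{v:.9g}\n")


def _read_binary(path: Path) -> Recording:
    with open(path, "rb") as fh:
        head = fh.read(8)
        if head != MAGIC:
            raise ParseError(f"{path}: bad magic {head!r}")
        version, fs, start_time = struct.unpack("<Idd", fh.read(4 + 8 + 8))
        if version != _VERSION:
            raise ParseError(f"{path}: unsupported container version {version}")
        kind = fh.read(4).rstrip(b"\x00").decode("ascii")
        (n,) = struct.unpack("<Q", fh.read(8))
        (n_markers,) = struct.unpack("<I", fh.read(4))
        markers = {}
        for _ in range(n_markers):
            (key_len,) = struct.unpack("<H", fh.read(2))
            key = fh.read(key_len).decode("utf-8")
            (t,) = struct.unpack("<d", fh.read(8))
            markers[key] = t
        samples = np.fromfile(fh, dtype="<f8", count=n)
        if samples.size != n:
            raise ParseError(f"{path}: truncated sample block ({samples.size}/{n})")
    return Recording(samples=samples, fs=fs, kind=kind,
                     start_time=start_time, markers=markers)


def _write_binary(rec: Recording, path: Path) -> None:
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<Idd", _VERSION, rec.fs, rec.start_time))
        fh.write(rec.kind.encode("ascii").ljust(4, b"\x00"))
        fh.write(struct.pack("<Q", rec.n))
        fh.write(struct.pack("<I", len(rec.markers)))
        for key, t in sorted(rec.markers.items()):
            kb = key.encode("utf-8")
            fh.write(struct.pack("<H", len(kb)))
            fh.write(kb)
            fh.write(struct.pack("<d", t))
        rec.samples.astype("<f8").tofile(fh)


def write_events(ev: EventSet, path: str | Path) -> Path:
    """Write an event table as TSV with threshold/baseline metadata."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# seizlfp events v1\n")
        fh.write(f"# threshold_mv={ev.threshold!r}\n")
        fh.write(f"# baseline_mean_mv={ev.baseline.mean!r}\n")
        fh.write(f"# baseline_sd_mv={ev.baseline.sd!r}\n")
        fh.write(
            f"# baseline_window_s={ev.baseline.window[0]!r},{ev.baseline.window[1]!r}\n"
        )
        fh.write(f"# source_duration_s={ev.source_duration!r}\n")
        fh.write("time_s\tamplitude_mv\n")
        for t, a in zip(ev.times, ev.amplitudes):
            fh.write(f"{t:.9g}\t{a:.9g}\n")
    return path


def read_events(path: str | Path) -> EventSet:
    """Read an event table written by :func:`write_events`."""
    path = Path(path)
    meta: dict = {}
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                key, _, value = body.partition("=")
                if value:
                    meta[key.strip()] = value.strip()
            elif line != "time_s\tamplitude_mv":
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ParseError(f"{path}: bad event row {line!r}")
                rows.append((float(parts[0]), float(parts[1])))
    try:
        w0, w1 = (float(x) for x in meta["baseline_window_s"].split(","))
        baseline = BaselineStats(
            mean=float(meta["baseline_mean_mv"]),
            sd=float(meta["baseline_sd_mv"]),
            window=(w0, w1),
        )
        return EventSet(
            times=np.array([r[0] for r in rows]),
            amplitudes=np.array([r[1] for r in rows]),
            threshold=float(meta["threshold_mv"]),
            baseline=baseline,
            source_duration=float(meta["source_duration_s"]),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing metadata field {exc}") from exc
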
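"""Reading and writing current traces and event tables.

Two trace formats are supported natively:

* tabular text — a ``# key: value`` header block followed by two columns
  (``time_s``, ``current_pA``); human-readable, round-trips to ~1e-6 pA;
* binary — magic ``SYNPORE1``, a JSON header (sampling rate, sample count,
  metadata) and float32 samples; compact and lossless at float32 precision.

Axon ABF files are ingested through the optional ``pyabf`` reader and
normalized to :class:`~synpore.simulate.CurrentTrace`.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CurrentTrace, GroundTruthEvent

_MAGIC = b"SYNPORE1"


class TraceParseError(ValueError):
    """Malformed or truncated trace file."""


def write_trace_text(trace: CurrentTrace, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# synpore trace v1\n")
        fh.write(f"# sampling_rate_Hz: {trace.sampling_rate!r}\n")
        fh.write(f"# n_samples: {trace.samples.size}\n")
        for key, value in sorted(trace.metadata.items()):
            fh.write(f"# meta {key}: {json.dumps(value)}\n")
        fh.write("# columns: time_s current_pA\n")
        np.savetxt(fh, np.column_stack([trace.times, trace.samples]), fmt="%.9f\t%.6f")


def read_trace_text(path) -> CurrentTrace:
    path = Path(path)
    sampling_rate = None
    n_expected = None
    metadata = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            try:
                if body.startswith("sampling_rate_Hz:"):
                    sampling_rate = float(body.split(":", 1)[1])
                elif body.startswith("n_samples:"):
                    n_expected = int(body.split(":", 1)[1])
                elif body.startswith("meta "):
                    key, _, raw = body[5:].partition(":")
                    metadata[key.strip()] = json.loads(raw)
            except (ValueError, json.JSONDecodeError) as exc:
                raise TraceParseError(f"{path}:{lineno}: malformed header line {line!r}") from exc
    try:
        data = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise TraceParseError(f"{path}: malformed data block: {exc}") from exc
    if sampling_rate is None:
        raise TraceParseError(f"{path}: missing sampling_rate_Hz header")
    if data.size and data.shape[1] != 2:
        raise TraceParseError(f"{path}: expected two columns, got {data.shape[1]}")
    samples = data[:, 1] if data.size else np.empty(0)
    if n_expected is not None and n_expected != samples.size:
        raise TraceParseError(
            f"{path}: header declares {n_expected} samples, file holds {samples.size}"
        )
    return CurrentTrace(samples, sampling_rate, metadata)


def write_trace_binary(trace: CurrentTrace, path) -> None:
    header = json.dumps(
        {
            "version": 1,
            "sampling_rate_Hz": trace.sampling_rate,
            "n_samples": int(trace.samples.size),
            "metadata": trace.metadata,
        }
    ).encode()
    with Path(path).open("wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<I", len(header)))
        fh.write(header)
        fh.write(trace.samples.astype("<f4").tobytes())


def read_trace_binary(path) -> CurrentTrace:
    path = Path(path)
    with path.open("rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise TraceParseError(f"{path}: bad magic {magic!r} (offset 0)")
        raw_len = fh.read(4)
        if len(raw_len) != 4:
            raise TraceParseError(f"{path}: truncated header length (offset {len(_MAGIC)})")
        (hlen,) = struct.unpack("<I", raw_len)
        raw_header = fh.read(hlen)
        if len(raw_header) != hlen:
            raise TraceParseError(f"{path}: truncated JSON header")
        try:
            header = json.loads(raw_header)
        except json.JSONDecodeError as exc:
            raise TraceParseError(f"{path}: malformed JSON header: {exc}") from exc
        n = int(header["n_samples"])
        payload = fh.read(4 * n)
        if len(payload) != 4 * n:
            raise TraceParseError(
                f"{path}: expected {n} float32 samples, found {len(payload) // 4}"
            )
        samples = np.frombuffer(payload, dtype="<f4").astype(np.float64)
    return CurrentTrace(samples, float(header["sampling_rate_Hz"]), header.get("metadata", {}))


def write_trace(trace: CurrentTrace, path, format: str | None = None) -> None:
    """Write a trace; format inferred from suffix (.txt/.tsv text, else binary)."""
    if format is None:
        format = "text" if str(path).endswith((".txt", ".tsv", ".dat")) else "binary"
    if format == "text":
        write_trace_text(trace, path)
    elif format == "binary":
        write_trace_binary(trace, path)
    else:
        raise ValueError(f"unknown trace format {format!r}")


def read_trace(path, format: str | None = None) -> CurrentTrace:
    """Read a trace; sniffs binary magic, falls back to text, or reads ABF."""
    path = Path(path)
    if format is None:
        if path.suffix.lower() == ".abf":
            format = "abf"
        else:
            with path.open("rb") as fh:
                format = "binary" if fh.read(len(_MAGIC)) == _MAGIC else "text"
    if format == "binary":
        return read_trace_binary(path)
    if format == "text":
        return read_trace_text(path)
    if format == "abf":
        return read_trace_abf(path)
    raise ValueError(f"unknown trace format {format!r}")


def read_trace_abf(path, channel: int = 0, sweep: int = 0) -> CurrentTrace:
    """Load one sweep of an Axon ABF file (requires the optional pyabf extra)."""
    try:
        import pyabf
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading ABF files requires pyabf (`pip install synpore[abf]`)"
        ) from exc
    abf = pyabf.ABF(str(path))  # pragma: no cover
    abf.setSweep(sweep, channel=channel)  # pragma: no cover
    meta = {"source": str(path), "abf_sweep": sweep, "abf_channel": channel}  # pragma: no cover
    return CurrentTrace(np.asarray(abf.sweepY, float), float(abf.dataRate), meta)  # pragma: no cover


def write_ground_truth(events: list[GroundTruthEvent], path) -> None:
    frame = pd.DataFrame(
        {
            "class": [e.label for e in events],
            "start_s": [e.start_s for e in events],
            "dwell_ms": [e.dwell_ms for e in events],
            "amplitude_pA": [e.amplitude_pA for e in events],
        }
    )
    frame.to_csv(path, index=False, float_format="%.9g")


def read_ground_truth(path) -> list[GroundTruthEvent]:
    frame = pd.read_csv(path)
    return [
        GroundTruthEvent(c, float(s), float(d), float(a))
        for c, s, d, a in zip(
            frame["class"], frame["start_s"], frame["dwell_ms"], frame["amplitude_pA"]
        )
    ]
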
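"""Recording and packet-stream I/O.

Two on-disk formats are exchanged by the toolkit:

* **Recordings** — CSV files with a ``time_s,ch1..chN,label`` header, preceded
  by ``#``-prefixed metadata lines (user id, sampling rate, gesture label).
  These hold labeled multi-channel sEMG envelope signals, the unit of
  training data.

* **Packet streams** — JSON-lines files, one object per line with keys
  ``ts_ms`` (milliseconds since stream epoch), ``user_id`` and ``ch`` (one
  envelope sample per channel, mV). This mirrors a lossy sensor transport:
  the reader drops malformed or out-of-order lines and counts them instead
  of failing, since rapid throughput is prioritized over guaranteed
  delivery.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import InvalidArgumentError, ParseError, ShapeError

__all__ = [
    "Recording",
    "SensorPacket",
    "PacketStreamReader",
    "read_recording",
    "write_recording",
    "packets_from_recording",
    "recording_from_packets",
    "read_packet_stream",
    "write_packet_stream",
]

_FORMAT_MAGIC = "gesturekit-recording"
_FORMAT_VERSION = 1


@dataclass
class Recording:
    """A timestamped multi-channel envelope signal for one user.

    Parameters
    ----------
    samples
        Array of shape ``(n_samples, n_channels)``, envelope amplitude in mV.
    sampling_rate
        Samples per second (the hardware streams at 50 Hz).
    user_id
        Owner of the recording.
    gesture_id
        Optional gesture label covering the whole recording.
    """

    samples: np.ndarray
    sampling_rate: float
    user_id: str = "anon"
    gesture_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.size == 0:
            self.samples = self.samples.reshape(0, self.samples.shape[-1] if self.samples.ndim == 2 else 0)
        if self.sampling_rate <= 0:
            raise InvalidArgumentError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("recording samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times_s(self) -> np.ndarray:
        """Per-sample time axis in seconds (sample k at k / sampling_rate)."""
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class SensorPacket:
    """One transport packet: a single multi-channel sample with provenance."""

    ts_ms: int
    user_id: str
    values: tuple[float, ...]

    @property
    def n_channels(self) -> int:
        return len(self.values)


def write_recording(rec: Recording, destination) -> None:
    """Write a recording as a metadata-headed CSV file.

    Layout: ``#`` metadata lines, then a ``time_s,ch1..chN,label`` header,
    then one row per sample. Floats are written with ``repr`` precision so
    the round trip is exact in float64.
    """
    buf = io.StringIO()
    buf.write(f"# {_FORMAT_MAGIC} v{_FORMAT_VERSION}\n")
    buf.write(f"# user_id={rec.user_id}\n")
    buf.write(f"# sampling_rate={rec.sampling_rate!r}\n")
    buf.write(f"# n_channels={rec.n_channels}\n")
    if rec.gesture_id is not None:
        buf.write(f"# gesture_id={rec.gesture_id}\n")
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["time_s"] + [f"ch{i + 1}" for i in range(rec.n_channels)] + ["label"])
    label = rec.gesture_id if rec.gesture_id is not None else ""
    for k in range(rec.n_samples):
        row = [repr(k / rec.sampling_rate)] + [repr(float(v)) for v in rec.samples[k]] + [label]
        writer.writerow(row)
    Path(destination).write_text(buf.getvalue())


def read_recording(source) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises
    ------
    ParseError
        On a malformed header, a ragged row, or a non-numeric cell; the error
        names the offending 1-based line number.
    """
    text = Path(source).read_text()
    meta: dict[str, str] = {}
    data_lines: list[tuple[int, str]] = []
    header_cols: list[str] | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        if header_cols is None:
            header_cols = next(csv.reader([line]))
            if not header_cols or header_cols[0] != "time_s" or header_cols[-1] != "label":
                raise ParseError("expected header 'time_s,ch1..chN,label'", line=lineno)
            continue
        data_lines.append((lineno, line))

    if header_cols is None:
        raise ParseError("no CSV header found", line=None)
    if "sampling_rate" not in meta:
        raise ParseError("missing '# sampling_rate=' metadata line", line=None)

    n_channels = len(header_cols) - 2
    declared = meta.get("n_channels")
    if declared is not None and int(declared) != n_channels:
        raise ParseError(
            f"declared n_channels={declared} but header has {n_channels} channel columns",
            line=None,
        )

    samples = np.empty((len(data_lines), n_channels), dtype=float)
    labels: set[str] = set()
    for i, (lineno, line) in enumerate(data_lines):
        cells = next(csv.reader([line]))
        if len(cells) != n_channels + 2:
            raise ParseError(
                f"expected {n_channels + 2} cells, got {len(cells)}", line=lineno
            )
        try:
            samples[i] = [float(c) for c in cells[1:-1]]
        except ValueError as exc:
            raise ParseError(f"non-numeric cell: {exc}", line=lineno) from None
        if cells[-1]:
            labels.add(cells[-1])

    if len(data_lines) == 0:
        samples = np.empty((0, n_channels), dtype=float)
    gesture_id = meta.get("gesture_id")
    if gesture_id is None and len(labels) == 1:
        gesture_id = labels.pop()
    return Recording(
        samples=samples,
        sampling_rate=float(meta["sampling_rate"]),
        user_id=meta.get("user_id", "anon"),
        gesture_id=gesture_id,
    )


def packets_from_recording(rec: Recording) -> list[SensorPacket]:
    """Explode a recording into one packet per sample.

    Sample ``k`` gets timestamp ``round(1000 * k / sampling_rate)`` ms, so a
    50 Hz recording yields consecutive timestamps 20 ms apart.
    """
    return [
        SensorPacket(
            ts_ms=int(round(1000.0 * k / rec.sampling_rate)),
            user_id=rec.user_id,
            values=tuple(float(v) for v in rec.samples[k]),
        )
        for k in range(rec.n_samples)
    ]


def recording_from_packets(
    packets: Sequence[SensorPacket], sampling_rate: float, gesture_id: str | None = None
) -> Recording:
    """Inverse of :func:`packets_from_recording` (exact round trip)."""
    packets = list(packets)
    if not packets:
        return Recording(samples=np.empty((0, 0)), sampling_rate=sampling_rate)
    n_channels = packets[0].n_channels
    for p in packets:
        if p.n_channels != n_channels:
            raise ShapeError(
                f"packet channel count changed mid-stream: expected {n_channels}, got {p.n_channels}"
            )
    samples = np.array([p.values for p in packets], dtype=float)
    return Recording(
        samples=samples,
        sampling_rate=sampling_rate,
        user_id=packets[0].user_id,
        gesture_id=gesture_id,
    )


def write_packet_stream(packets: Iterable[SensorPacket], destination) -> None:
    """Write packets as JSON lines: ``{"ts_ms": ..., "user_id": ..., "ch": [...]}``."""
    with open(destination, "w") as fh:
        for p in packets:
            fh.write(json.dumps({"ts_ms": p.ts_ms, "user_id": p.user_id, "ch": list(p.values)}))
            fh.write("\n")


@dataclass
class PacketStreamReader:
    """Loss-tolerant JSON-lines packet reader.

    Iterating yields valid :class:`SensorPacket` objects in file order.
    Malformed lines (bad JSON, missing keys, wrong channel count,
    non-numeric values) and out-of-order timestamps are *dropped and
    counted*, never fatal — mirroring a UDP-like transport where delivery
    is not guaranteed. After exhaustion, if more than half the lines were
    dropped a ``UserWarning`` is emitted.

    Attributes
    ----------
    dropped : number of lines discarded so far.
    total : number of non-empty lines seen so far.
    """

    source: object
    expected_channels: int
    dropped: int = 0
    total: int = 0
    _last_ts: int | None = field(default=None, repr=False)

    def __iter__(self) -> Iterator[SensorPacket]:
        try:
            fh = open(self.source, "r", errors="replace")
        except OSError as exc:
            raise ParseError(f"cannot open packet stream: {exc}") from exc
        with fh:
            for line in fh:
                if not line.strip():
                    continue
                self.total += 1
                packet = self._parse_line(line)
                if packet is None:
                    self.dropped += 1
                    continue
                self._last_ts = packet.ts_ms
                yield packet
        if self.total and self.dropped / self.total > 0.5:
            warnings.warn(
                f"dropped {self.dropped} of {self.total} packet lines (>50%)",
                UserWarning,
                stacklevel=2,
            )

    def _parse_line(self, line: str) -> SensorPacket | None:
        try:
            obj = json.loads(line)
            ts = int(obj["ts_ms"])
            user = str(obj["user_id"])
            ch = [float(v) for v in obj["ch"]]
        except (json.JSONDecodeError, KeyError, TypeError, ValueError, OverflowError):
            return None
        if len(ch) != self.expected_channels:
            return None
        if any(not np.isfinite(v) for v in ch):
            return None
        if self._last_ts is not None and ts < self._last_ts:
            return None  # out-of-order: drop, do not re-sort
        return SensorPacket(ts_ms=ts, user_id=user, values=tuple(ch))


def read_packet_stream(source, expected_channels: int) -> PacketStreamReader:
    """Open a JSON-lines packet stream; returns an iterable reader that
    exposes ``dropped`` / ``total`` counters (see :class:`PacketStreamReader`)."""
    return PacketStreamReader(source=source, expected_channels=expected_channels)
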
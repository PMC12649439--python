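"""Online inference over sensor packet streams.

A per-user ring buffer holds the last ``window_len`` raw samples; every
``stride`` new samples (once the buffer is full) the window is standardized
with the artifact's stored scaler parameters — the same values fit at
training time — and classified. Emissions are therefore elementwise
identical to running the batch pipeline over the concatenated stream
(streaming ≡ batch).

Packet loss is tolerated: a timestamp jump greater than twice the nominal
sample period is treated as a stream gap, which resets the buffer so no
window ever mixes pre- and post-gap samples.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .errors import ShapeError
from .model import ModelArtifact, predict_window
from .preprocessing import WindowingConfig, apply_scaler
from .signal_io import SensorPacket

__all__ = ["Emission", "StreamClassifier", "stream_infer", "latency_summary"]


@dataclass(frozen=True)
class Emission:
    """One streaming classification: the window ending at ``ts_ms``."""

    ts_ms: int
    gesture: str
    probabilities: np.ndarray
    buffer_duration_s: float = 0.0  # instrumentation (0 when off)
    infer_duration_s: float = 0.0


class StreamClassifier:
    """Stateful online classifier over one user's packet stream.

    Feed packets one at a time with :meth:`feed`; each call returns the
    (possibly empty) list of emissions it triggered. Instrumentation, when
    enabled, records per-emission buffer-update and inference durations
    without changing the emissions themselves.
    """

    def __init__(
        self,
        artifact: ModelArtifact,
        windowing: WindowingConfig = WindowingConfig(),
        instrument: bool = False,
    ):
        self.artifact = artifact
        self.windowing = windowing
        self.instrument = instrument
        self.n_channels = int(artifact.sensor_config["n_channels"])
        self.period_ms = 1000.0 / float(artifact.sensor_config["sampling_rate"])
        self._buffer: list[tuple[float, ...]] = []
        self._samples_seen = 0
        self._last_ts: int | None = None

    def reset(self) -> None:
        """Clear the buffer (called automatically on a stream gap)."""
        self._buffer.clear()
        self._samples_seen = 0

    def feed(self, packet: SensorPacket) -> list[Emission]:
        if packet.n_channels != self.n_channels:
            raise ShapeError(
                f"packet has {packet.n_channels} channels, artifact expects {self.n_channels}"
            )
        t0 = time.perf_counter() if self.instrument else 0.0
        if (
            self._last_ts is not None
            and packet.ts_ms - self._last_ts > 2.0 * self.period_ms
        ):
            self.reset()
        self._last_ts = packet.ts_ms
        self._buffer.append(packet.values)
        wl = self.windowing.window_len
        if len(self._buffer) > wl:
            self._buffer.pop(0)
        self._samples_seen += 1
        t1 = time.perf_counter() if self.instrument else 0.0

        if self._samples_seen < wl or (self._samples_seen - wl) % self.windowing.stride != 0:
            return []
        raw = np.array(self._buffer, dtype=float)  # (window_len, channels)
        window = apply_scaler(raw, self.artifact.scaler).T  # (channels, window_len)
        gesture, probs = predict_window(self.artifact, window)
        t2 = time.perf_counter() if self.instrument else 0.0
        return [
            Emission(
                ts_ms=packet.ts_ms,
                gesture=gesture,
                probabilities=probs,
                buffer_duration_s=t1 - t0,
                infer_duration_s=t2 - t1,
            )
        ]


def stream_infer(
    packets: Iterable[SensorPacket],
    artifact: ModelArtifact,
    windowing: WindowingConfig = WindowingConfig(),
    instrument: bool = False,
) -> Iterator[Emission]:
    """Classify a packet stream lazily; yields one emission per stride."""
    clf = StreamClassifier(artifact, windowing, instrument=instrument)
    for packet in packets:
        yield from clf.feed(packet)


def latency_summary(emissions: Iterable[Emission]) -> dict[str, float]:
    """Mean and 95th-percentile per-stage durations over instrumented
    emissions, for reporting only (wall-clock, hence hardware-dependent)."""
    ems = list(emissions)
    buf = np.array([e.buffer_duration_s for e in ems], dtype=float)
    if buf.size == 0:
        return {"n": 0}
    inf = np.array([e.infer_duration_s for e in ems], dtype=float)
    return {
        "n": int(buf.size),
        "buffer_mean_s": float(buf.mean()),
        "buffer_p95_s": float(np.percentile(buf, 95)),
        "infer_mean_s": float(inf.mean()) if inf.size else 0.0,
        "infer_p95_s": float(np.percentile(inf, 95)) if inf.size else 0.0,
    }
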
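"""Vibrotactile pattern encoding for a 10-motor arm sleeve.

Messages — letters or recognized gesture labels — are rendered as
spatiotemporal vibration patterns on an array of independently addressable
ERM (eccentric rotating mass) coin motors. A symbol's pattern is a timed
set of motor activation events; a message is the concatenation of its
symbols' patterns separated by a fixed inter-symbol gap, so the wearer can
segment the stream by feel. Encoding maps are fully customizable (any
injective symbol-to-pattern dictionary); this module ships a default
letter map and a generator that assigns distinct patterns to a user's
gesture bank, both using single-motor pulses with position and duration
coding.

The decoder inverts :func:`encode` exactly (``decode(encode(m)) == m``)
via maximal-munch matching; its real-world counterpart is a human wearer,
so the software decoder exists to verify codec integrity.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import CapacityError, DecodeError, InvalidArgumentError

__all__ = [
    "MotorEvent",
    "HapticPattern",
    "EncodingMap",
    "encode",
    "decode",
    "map_from_gesture_bank",
    "default_letter_map",
]

DEFAULT_N_MOTORS = 10


@dataclass(frozen=True, order=True)
class MotorEvent:
    """One motor activation: which motor, when, for how long, how strong."""

    start_ms: int
    motor: int
    duration_ms: int
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.motor < 0:
            raise InvalidArgumentError("motor index must be >= 0")
        if self.duration_ms <= 0:
            raise InvalidArgumentError("event duration must be > 0 ms")
        if not (0.0 < self.intensity <= 1.0):
            raise InvalidArgumentError("intensity must lie in (0, 1]")

    def shifted(self, offset_ms: int) -> "MotorEvent":
        return MotorEvent(self.start_ms + offset_ms, self.motor, self.duration_ms, self.intensity)


@dataclass(frozen=True)
class HapticPattern:
    """A timed set of motor events plus the pattern's total duration."""

    events: tuple[MotorEvent, ...]
    total_duration_ms: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(sorted(self.events)))
        if self.total_duration_ms < 0:
            raise InvalidArgumentError("total_duration_ms must be >= 0")
        if self.events:
            end = max(e.start_ms + e.duration_ms for e in self.events)
            if self.total_duration_ms < end:
                raise InvalidArgumentError(
                    f"total_duration_ms {self.total_duration_ms} < last event end {end}"
                )
        per_motor: dict[int, list[MotorEvent]] = {}
        for e in self.events:
            per_motor.setdefault(e.motor, []).append(e)
        for motor, evs in per_motor.items():
            evs.sort()
            for a, b in zip(evs, evs[1:]):
                if b.start_ms < a.start_ms + a.duration_ms:
                    raise InvalidArgumentError(
                        f"overlapping events on motor {motor} at {b.start_ms} ms"
                    )

    def max_motor(self) -> int:
        return max((e.motor for e in self.events), default=-1)

    def to_dict(self) -> dict:
        return {
            "total_duration_ms": self.total_duration_ms,
            "events": [
                {
                    "motor": e.motor,
                    "start_ms": e.start_ms,
                    "duration_ms": e.duration_ms,
                    "intensity": e.intensity,
                }
                for e in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "HapticPattern":
        return cls(
            events=tuple(
                MotorEvent(
                    start_ms=int(e["start_ms"]),
                    motor=int(e["motor"]),
                    duration_ms=int(e["duration_ms"]),
                    intensity=float(e.get("intensity", 1.0)),
                )
                for e in d["events"]
            ),
            total_duration_ms=int(d["total_duration_ms"]),
        )


@dataclass
class EncodingMap:
    """An injective symbol -> pattern dictionary for one sleeve layout."""

    patterns: dict[str, HapticPattern]
    gap_ms: int = 100
    n_motors: int = DEFAULT_N_MOTORS

    def __post_init__(self) -> None:
        if self.gap_ms < 1:
            raise InvalidArgumentError("inter-symbol gap must be >= 1 ms")
        seen: dict[tuple, str] = {}
        for symbol, pattern in self.patterns.items():
            if not pattern.events:
                raise InvalidArgumentError(f"symbol {symbol!r} has an empty pattern")
            if pattern.max_motor() >= self.n_motors:
                raise InvalidArgumentError(
                    f"symbol {symbol!r} uses motor {pattern.max_motor()} but the sleeve "
                    f"has {self.n_motors} motors"
                )
            key = (pattern.events, pattern.total_duration_ms)
            if key in seen:
                raise InvalidArgumentError(
                    f"symbols {seen[key]!r} and {symbol!r} share an identical pattern "
                    "(map must be injective)"
                )
            seen[key] = symbol

    @property
    def alphabet(self) -> list[str]:
        return sorted(self.patterns.keys())

    def to_json(self) -> str:
        return json.dumps(
            {
                "gap_ms": self.gap_ms,
                "n_motors": self.n_motors,
                "patterns": {s: p.to_dict() for s, p in sorted(self.patterns.items())},
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "EncodingMap":
        d = json.loads(text)
        return cls(
            patterns={s: HapticPattern.from_dict(p) for s, p in d["patterns"].items()},
            gap_ms=int(d["gap_ms"]),
            n_motors=int(d["n_motors"]),
        )


def encode(message: Sequence[str], emap: EncodingMap) -> HapticPattern:
    """Concatenate the symbols' patterns, separated by the inter-symbol gap.

    Total duration = sum of symbol durations + (len - 1) gaps; an empty
    message encodes to the empty pattern of duration 0.
    """
    events: list[MotorEvent] = []
    offset = 0
    for i, symbol in enumerate(message):
        if symbol not in emap.patterns:
            raise InvalidArgumentError(f"unknown symbol {symbol!r} (not in the encoding map)")
        pattern = emap.patterns[symbol]
        if i > 0:
            offset += emap.gap_ms
        events.extend(e.shifted(offset) for e in pattern.events)
        offset += pattern.total_duration_ms
    return HapticPattern(events=tuple(events), total_duration_ms=offset)


def decode(pattern: HapticPattern, emap: EncodingMap) -> list[str]:
    """Invert :func:`encode`: recover the symbol sequence.

    Maximal-munch: at each offset the candidate symbol whose shifted events
    exactly match the next events of the stream — preferring more events,
    then longer duration — is consumed. An unsegmentable stream raises
    :class:`DecodeError` naming the failing offset in ms.
    """
    remaining = list(pattern.events)  # already sorted
    out: list[str] = []
    offset = 0
    while remaining:
        candidates = []
        for symbol, sym_pattern in emap.patterns.items():
            shifted = tuple(e.shifted(offset) for e in sym_pattern.events)
            if tuple(remaining[: len(shifted)]) == shifted:
                candidates.append((len(shifted), sym_pattern.total_duration_ms, symbol))
        if not candidates:
            raise DecodeError(
                f"no symbol pattern matches event {remaining[0]}", offset_ms=offset
            )
        candidates.sort(reverse=True)
        n_events, duration, symbol = candidates[0]
        out.append(symbol)
        del remaining[:n_events]
        offset += duration + emap.gap_ms
    return out


def _pulse_pattern(
    motor: int, duration_ms: int, intensity: float, symbol_duration_ms: int
) -> HapticPattern:
    return HapticPattern(
        events=(MotorEvent(start_ms=0, motor=motor, duration_ms=duration_ms, intensity=intensity),),
        total_duration_ms=max(symbol_duration_ms, duration_ms),
    )


def map_from_gesture_bank(
    gestures: Sequence[str],
    n_motors: int = DEFAULT_N_MOTORS,
    durations_ms: Sequence[int] = (300,),
    intensities: Sequence[float] = (1.0,),
    symbol_duration_ms: int = 300,
    gap_ms: int = 100,
    seed: int = 0,
) -> EncodingMap:
    """Assign each gesture a distinct single-motor pulse pattern.

    The pattern space is the (motor, duration, intensity) grid, shuffled
    deterministically under ``seed``; requesting more symbols than the grid
    holds raises :class:`CapacityError`. Injectivity holds by construction
    (distinct grid points give distinct patterns).
    """
    gestures = list(gestures)
    if not gestures:
        raise InvalidArgumentError("need at least one gesture")
    if len(set(gestures)) != len(gestures):
        raise InvalidArgumentError("gesture names must be unique")
    grid = [
        (m, d, i) for m in range(n_motors) for d in durations_ms for i in intensities
    ]
    if len(gestures) > len(grid):
        raise CapacityError(
            f"{len(gestures)} symbols requested but the style's pattern space holds "
            f"only {len(grid)} distinct patterns"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    order = rng.permutation(len(grid))
    patterns = {
        g: _pulse_pattern(*grid[order[k]], symbol_duration_ms=symbol_duration_ms)
        for k, g in enumerate(gestures)
    }
    return EncodingMap(patterns=patterns, gap_ms=gap_ms, n_motors=n_motors)


def default_letter_map(gap_ms: int = 100) -> EncodingMap:
    """A-Z on a 10-motor sleeve: single-motor pulses with position and
    duration coding (letters 0-9 short, 10-19 medium, 20-25 long pulses)."""
    durations = (150, 300, 450)
    patterns = {}
    for i, letter in enumerate(string.ascii_uppercase):
        motor = i % DEFAULT_N_MOTORS
        duration = durations[i // DEFAULT_N_MOTORS]
        patterns[letter] = _pulse_pattern(
            motor, duration, 1.0, symbol_duration_ms=duration
        )
    return EncodingMap(patterns=patterns, gap_ms=gap_ms, n_motors=DEFAULT_N_MOTORS)
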
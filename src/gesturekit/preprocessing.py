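"""Recording-to-window preprocessing.

Three stages turn recordings into model input:

1. *(optional)* envelope emulation for raw-mode signals: rectify, first-order
   low-pass at 3.6 Hz, decimate to 50 Hz — mirroring the analog envelope
   detector of the acquisition front-end;
2. z-score standardization, ``z = (x - mu) / sigma`` per channel, with the
   mean and standard deviation computed on training data only and persisted
   so deployment reuses exactly the same values;
3. sliding-window segmentation into fixed-length windows (default 32 samples
   with 50% overlap, i.e. stride 16), incomplete tails dropped.

Standardization is applied to the continuous recording before segmentation;
because the map is linear and per-channel, the order is algebraically
equivalent to standardizing each window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import lfilter

from .errors import InvalidArgumentError, ShapeError
from .signal_io import Recording

__all__ = [
    "WindowingConfig",
    "ScalerParams",
    "WindowBatch",
    "fit_scaler",
    "apply_scaler",
    "segment_windows",
    "batch_from_recordings",
    "envelope_from_raw",
]


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window geometry: 32-sample windows at 50% overlap by default."""

    window_len: int = 32
    overlap_fraction: float = 0.5
    label_rule: str = "majority"  # "majority" | "center"

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise InvalidArgumentError(f"window_len must be >= 1, got {self.window_len}")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise InvalidArgumentError(
                f"overlap_fraction must be in [0, 1), got {self.overlap_fraction}"
            )
        if self.label_rule not in ("majority", "center"):
            raise InvalidArgumentError(f"unknown label_rule {self.label_rule!r}")
        if self.stride < 1:
            raise InvalidArgumentError("stride rounds to 0; increase window_len or reduce overlap")

    @property
    def stride(self) -> int:
        return int(round(self.window_len * (1.0 - self.overlap_fraction)))


@dataclass(eq=False)
class ScalerParams:
    """Per-channel standardization parameters, fit on training data only.

    Uses the population standard deviation (ddof=0). Channels with zero
    variance are flagged degenerate and guarded with ``epsilon`` so the
    transform maps them to all-zeros instead of dividing by zero.
    """

    mean: np.ndarray
    std: np.ndarray
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.std = np.asarray(self.std, dtype=float).ravel()
        if self.mean.shape != self.std.shape:
            raise ShapeError(f"mean/std shape mismatch: {self.mean.shape} vs {self.std.shape}")
        if np.any(self.std < 0):
            raise InvalidArgumentError("standard deviations must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.mean.shape[0]

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of zero-variance (constant) channels."""
        return self.std == 0.0

    @property
    def safe_std(self) -> np.ndarray:
        return np.maximum(self.std, self.epsilon)

    def transform(self, data: np.ndarray) -> np.ndarray:
        return apply_scaler(data, self)

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        """Undo the transform; exact (within 1e-9) for non-degenerate channels."""
        z = np.asarray(z, dtype=float)
        _check_channels(z, self.n_channels)
        return z * self.safe_std + self.mean

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "epsilon": self.epsilon,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScalerParams":
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            std=np.asarray(d["std"], dtype=float),
            epsilon=float(d.get("epsilon", 1e-8)),
        )


def _as_samples(obj) -> np.ndarray:
    """Accept a Recording or a (time, channels) array."""
    if isinstance(obj, Recording):
        return obj.samples
    return np.asarray(obj, dtype=float)


def _check_channels(data: np.ndarray, expected: int) -> None:
    if data.ndim < 1 or data.shape[-1] != expected:
        raise ShapeError(
            f"channel mismatch: expected {expected} channels, got shape {data.shape}"
        )


def fit_scaler(training_data: Sequence[Recording] | Sequence[np.ndarray] | np.ndarray) -> ScalerParams:
    """Compute per-channel mean and population standard deviation.

    ``training_data`` may be a single (time, channels) array, a Recording,
    or a sequence of either; all samples are pooled over time.
    """
    if isinstance(training_data, (Recording, np.ndarray)):
        training_data = [training_data]
    arrays = [_as_samples(r) for r in training_data]
    arrays = [a for a in arrays if a.size]
    if not arrays:
        raise InvalidArgumentError("cannot fit a scaler on empty training data")
    n_channels = arrays[0].shape[-1]
    for a in arrays:
        _check_channels(a, n_channels)
    pooled = np.concatenate([a.reshape(-1, n_channels) for a in arrays], axis=0)
    if pooled.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 samples per channel to fit a scaler")
    return ScalerParams(mean=pooled.mean(axis=0), std=pooled.std(axis=0, ddof=0))


def apply_scaler(data, params: ScalerParams) -> np.ndarray:
    """Standardize ``(x - mu) / max(sigma, epsilon)`` per channel (last axis).

    A pure function: never mutates ``params``. Accepts any array whose last
    axis is the channel axis, or a Recording (standardizing its samples).
    """
    x = _as_samples(data)
    _check_channels(x, params.n_channels)
    return (x - params.mean) / params.safe_std


@dataclass(eq=False)
class WindowBatch:
    """Fixed-length standardized windows plus integer class labels.

    ``windows`` has shape (n_windows, n_channels, window_len); ``labels``
    holds class indices in ``[0, n_classes)``.
    """

    windows: np.ndarray
    labels: np.ndarray
    user_id: str | None = None

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.windows.ndim != 3:
            raise ShapeError(
                f"windows must be (n, channels, window_len), got shape {self.windows.shape}"
            )
        if self.labels.shape != (self.windows.shape[0],):
            raise ShapeError(
                f"labels shape {self.labels.shape} does not match {self.windows.shape[0]} windows"
            )

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]

    @property
    def window_len(self) -> int:
        return self.windows.shape[2]

    @staticmethod
    def concatenate(batches: Sequence["WindowBatch"]) -> "WindowBatch":
        batches = [b for b in batches if len(b)]
        if not batches:
            raise InvalidArgumentError("cannot concatenate zero non-empty batches")
        users = {b.user_id for b in batches}
        return WindowBatch(
            windows=np.concatenate([b.windows for b in batches], axis=0),
            labels=np.concatenate([b.labels for b in batches], axis=0),
            user_id=users.pop() if len(users) == 1 else None,
        )


def segment_windows(
    rec: Recording | np.ndarray,
    cfg: WindowingConfig = WindowingConfig(),
    label: int = 0,
    sample_labels: Sequence[int] | None = None,
    user_id: str | None = None,
) -> WindowBatch:
    """Cut a recording into overlapping fixed-length windows.

    Window starts are ``{0, stride, 2*stride, ...}`` while the full window
    fits; the incomplete tail is dropped. With per-sample labels, each
    window is labeled by majority vote (ties broken by the center sample)
    or by the center sample directly, per ``cfg.label_rule``; otherwise
    ``label`` is broadcast to every window.
    """
    x = _as_samples(rec)
    if isinstance(rec, Recording) and user_id is None:
        user_id = rec.user_id
    if x.ndim != 2:
        x = np.atleast_2d(x)
    n, c = x.shape
    wl, stride = cfg.window_len, cfg.stride
    if n < wl:
        return WindowBatch(
            windows=np.empty((0, c, wl)), labels=np.empty(0, dtype=int), user_id=user_id
        )
    # (n - wl + 1, c, wl) view, subsampled every `stride` starts
    views = sliding_window_view(x, wl, axis=0)[::stride]
    windows = np.ascontiguousarray(views)  # copy out of the strided view
    starts = np.arange(windows.shape[0]) * stride
    if sample_labels is not None:
        sample_labels = np.asarray(sample_labels, dtype=int)
        if sample_labels.shape != (n,):
            raise ShapeError(
                f"sample_labels must have one entry per sample ({n}), got {sample_labels.shape}"
            )
        labels = np.array(
            [_window_label(sample_labels[s : s + wl], cfg.label_rule) for s in starts], dtype=int
        )
    else:
        labels = np.full(windows.shape[0], int(label), dtype=int)
    return WindowBatch(windows=windows, labels=labels, user_id=user_id)


def _window_label(window_labels: np.ndarray, rule: str) -> int:
    center = int(window_labels[len(window_labels) // 2])
    if rule == "center":
        return center
    values, counts = np.unique(window_labels, return_counts=True)
    winners = values[counts == counts.max()]
    if len(winners) == 1:
        return int(winners[0])
    return center if center in winners else int(winners.min())


def batch_from_recordings(
    recordings: Sequence[Recording],
    class_map: Mapping[str, int],
    cfg: WindowingConfig = WindowingConfig(),
    scaler: ScalerParams | None = None,
) -> WindowBatch:
    """Standardize and segment a set of recordings into one labeled batch.

    Each recording is windowed independently, so no window ever spans the
    boundary between two recordings. Labels come from ``class_map`` applied
    to each recording's ``gesture_id``.
    """
    if not recordings:
        raise InvalidArgumentError("no recordings given")
    batches = []
    for rec in recordings:
        if rec.gesture_id not in class_map:
            raise InvalidArgumentError(
                f"recording gesture {rec.gesture_id!r} missing from class map"
            )
        x = apply_scaler(rec.samples, scaler) if scaler is not None else rec.samples
        batches.append(
            segment_windows(x, cfg, label=class_map[rec.gesture_id], user_id=rec.user_id)
        )
    return WindowBatch.concatenate(batches)


def envelope_from_raw(
    raw: Recording,
    lowpass_cutoff: float = 3.6,
    target_rate: float = 50.0,
) -> Recording:
    """Emulate the analog envelope detector on a raw-mode recording.

    Rectify (absolute value), apply a first-order low-pass at
    ``lowpass_cutoff`` Hz (discrete RC filter, unit DC gain), then decimate
    to ``target_rate``. The output is nonnegative by construction: the
    filter has nonnegative coefficients and the rectified input is
    nonnegative.
    """
    if raw.sampling_rate <= 2.0 * lowpass_cutoff:
        raise InvalidArgumentError(
            f"raw sampling rate {raw.sampling_rate} Hz must exceed twice the "
            f"{lowpass_cutoff} Hz cutoff"
        )
    if lowpass_cutoff > target_rate / 2.0:
        raise InvalidArgumentError(
            f"cutoff {lowpass_cutoff} Hz is above the Nyquist rate of the "
            f"{target_rate} Hz target"
        )
    ratio = raw.sampling_rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise InvalidArgumentError(
            f"raw rate {raw.sampling_rate} Hz must be an integer multiple of the "
            f"target rate {target_rate} Hz"
        )
    rectified = np.abs(raw.samples)
    dt = 1.0 / raw.sampling_rate
    rc = 1.0 / (2.0 * np.pi * lowpass_cutoff)
    alpha = dt / (rc + dt)  # y[k] = y[k-1] + alpha * (x[k] - y[k-1])
    smoothed = lfilter([alpha], [1.0, alpha - 1.0], rectified, axis=0)
    decimated = smoothed[:: int(round(ratio))]
    return Recording(
        samples=decimated,
        sampling_rate=target_rate,
        user_id=raw.user_id,
        gesture_id=raw.gesture_id,
    )
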
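"""Synthetic multi-channel sEMG envelope generation.

The toolkit's classifier consumes *envelope* (ENV) signals: rectified,
low-pass-filtered sEMG magnitude sampled at 50 Hz on 4 forearm channels,
with amplitudes in the physiological 0-10 mV range. This module stands in
for hardware acquisition and human subjects by generating such envelopes
from a parametric model with two layers:

* a **gesture template** — per-channel activation profiles (trapezoid or
  gaussian burst, each with an onset, duration and peak amplitude) shared by
  everyone who performs the gesture;
* a **user phenotype** — the per-user physiology that makes sEMG so variable
  across individuals: per-channel amplitude gains (muscle strength,
  electrode impedance), timing jitter (motor timing), a row-stochastic
  channel-mixing matrix (electrode shift and crosstalk from adjacent
  muscles), additive noise and slow baseline drift.

A single ``variability_level`` knob scales every phenotype dispersion, so a
cohort can range from clones (level 0, used as the null case in the
personalization experiments) to strongly heterogeneous users.

All generation is a pure function of (template, phenotype, config, seed):
per-repetition random substreams are derived with ``numpy.random
.SeedSequence`` spawn keys, so datasets are bitwise reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidArgumentError, ShapeError
from .signal_io import Recording

__all__ = [
    "ChannelProfile",
    "GestureTemplate",
    "UserPhenotype",
    "SimConfig",
    "LabeledDataset",
    "sensor_gain",
    "make_gesture_bank",
    "sample_phenotypes",
    "synthesize_repetition",
    "synthesize_raw_repetition",
    "synthesize_dataset",
]

EMG_AMPLITUDE_MAX_MV = 10.0  # physiological sEMG envelope ceiling

# Dispersion scales applied per unit of variability_level. Chosen once to
# span the range from indistinguishable clones (level 0) to cohorts where
# channel identity is substantially scrambled across users (level >= 1).
_GAIN_LOG_SD = 0.4  # log-normal sd of per-channel amplitude gains
_TIMING_OFFSET_SD_S = 0.12  # across-user static timing offset sd, seconds
_JITTER_SD_S = 0.08  # within-user per-repetition jitter scale, seconds
_MIXING_MASS = 0.45  # mean off-diagonal mass of the channel-mixing matrix
_MIXING_MASS_CAP = 0.6  # a worn sleeve shifts electrodes partway, never fully swapping them
_NOISE_BASE_MV = 0.25  # envelope noise floor, mV
_NOISE_LOG_SD = 0.3  # across-user dispersion of the noise floor
_DRIFT_MV = 0.2  # baseline drift amplitude per unit variability, mV
_EFFORT_LOG_SD = 0.25  # within-user, per-repetition contraction-strength spread


def sensor_gain(r_kohm: float) -> float:
    """Envelope-mode amplifier gain for a potentiometer setting of ``r_kohm``.

    The acquisition front-end's gain follows ``G = 200 * R / 1 kOhm``; the
    simulator uses it to translate a configured resistance into an envelope
    amplitude multiplier.
    """
    if r_kohm < 0:
        raise InvalidArgumentError(f"resistance must be >= 0 kOhm, got {r_kohm}")
    return 200.0 * float(r_kohm)


@dataclass(frozen=True)
class ChannelProfile:
    """Activation profile of one channel within a gesture template.

    ``onset_fraction`` and ``duration_fraction`` are expressed as fractions
    of the repetition; ``peak_amplitude`` is in mV.
    """

    onset_fraction: float
    duration_fraction: float
    peak_amplitude: float
    shape: str = "trapezoid"  # "trapezoid" | "gaussian-burst"

    def __post_init__(self) -> None:
        if not (0.0 <= self.onset_fraction < 1.0):
            raise InvalidArgumentError(f"onset_fraction must be in [0,1), got {self.onset_fraction}")
        if not (0.0 < self.duration_fraction <= 1.0):
            raise InvalidArgumentError(
                f"duration_fraction must be in (0,1], got {self.duration_fraction}"
            )
        if self.onset_fraction + self.duration_fraction > 1.0 + 1e-12:
            raise InvalidArgumentError("onset_fraction + duration_fraction must be <= 1")
        if not (0.0 <= self.peak_amplitude <= EMG_AMPLITUDE_MAX_MV):
            raise InvalidArgumentError(
                f"peak_amplitude must lie in [0, {EMG_AMPLITUDE_MAX_MV}] mV, got {self.peak_amplitude}"
            )
        if self.shape not in ("trapezoid", "gaussian-burst"):
            raise InvalidArgumentError(f"unknown profile shape {self.shape!r}")


@dataclass(frozen=True)
class GestureTemplate:
    """Per-channel activation profiles defining one gesture's envelope."""

    gesture_id: str
    profiles: tuple[ChannelProfile, ...]
    baseline_amplitude: float = 0.05

    def __post_init__(self) -> None:
        if not self.profiles:
            raise InvalidArgumentError("template needs at least one channel profile")
        if self.baseline_amplitude < 0:
            raise InvalidArgumentError("baseline_amplitude must be >= 0")
        if not any(p.peak_amplitude > self.baseline_amplitude for p in self.profiles):
            raise InvalidArgumentError(
                "at least one channel must activate above baseline"
            )

    @property
    def n_channels(self) -> int:
        return len(self.profiles)

    def render(self, n_samples: int, duration_s: float, time_shift_s: float = 0.0) -> np.ndarray:
        """Render the noiseless activation envelope, shape (n_channels, n_samples).

        ``time_shift_s`` delays the whole gesture (used for timing jitter).
        """
        t = np.arange(n_samples) / (n_samples / duration_s) if duration_s > 0 else np.zeros(n_samples)
        tau = (t - time_shift_s) / duration_s  # normalized repetition time
        out = np.empty((self.n_channels, n_samples), dtype=float)
        for c, prof in enumerate(self.profiles):
            out[c] = self.baseline_amplitude + (
                prof.peak_amplitude - self.baseline_amplitude
            ) * _activation(tau, prof)
        return out


def _activation(tau: np.ndarray, prof: ChannelProfile) -> np.ndarray:
    """Unit-height activation curve on normalized time tau in [0, 1)."""
    onset, dur = prof.onset_fraction, prof.duration_fraction
    if prof.shape == "gaussian-burst":
        center = onset + dur / 2.0
        sd = dur / 4.0
        return np.exp(-0.5 * ((tau - center) / sd) ** 2)
    # trapezoid: linear rise / fall over 15% of the active duration each
    ramp = 0.15 * dur
    up = np.clip((tau - onset) / ramp, 0.0, 1.0)
    down = np.clip((onset + dur - tau) / ramp, 0.0, 1.0)
    return np.minimum(up, down)


@dataclass(frozen=True, eq=False)
class UserPhenotype:
    """Per-user physiology controlling inter-user signal variability."""

    user_id: str
    gains: np.ndarray  # per-channel amplitude multipliers, > 0
    timing_jitter_sd: float  # within-user per-repetition jitter, seconds
    channel_mixing: np.ndarray  # row-stochastic (rows sum to 1)
    noise_sd: float  # mV
    drift_amplitude: float = 0.0  # mV
    timing_offset_s: float = 0.0  # static habitual onset shift, seconds

    def __post_init__(self) -> None:
        object.__setattr__(self, "gains", np.asarray(self.gains, dtype=float))
        object.__setattr__(self, "channel_mixing", np.asarray(self.channel_mixing, dtype=float))
        if np.any(self.gains <= 0):
            raise InvalidArgumentError("phenotype gains must be > 0")
        m = self.channel_mixing
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != self.gains.shape[0]:
            raise ShapeError(
                f"channel_mixing must be square ({self.gains.shape[0]}x{self.gains.shape[0]}), got {m.shape}"
            )
        if np.any(m < 0):
            raise InvalidArgumentError("channel_mixing entries must be >= 0")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
            raise InvalidArgumentError("channel_mixing rows must sum to 1 within 1e-9")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if self.timing_jitter_sd < 0:
            raise InvalidArgumentError("timing_jitter_sd must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.gains.shape[0]


@dataclass(frozen=True)
class SimConfig:
    """Acquisition geometry and cohort-level variability for the simulator."""

    n_channels: int = 4
    sampling_rate: float = 50.0
    repetition_duration: float = 2.0  # seconds per gesture repetition
    variability_level: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise InvalidArgumentError("n_channels must be >= 1")
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be > 0")
        if self.repetition_duration <= 0:
            raise InvalidArgumentError("repetition_duration must be > 0")
        if self.variability_level < 0:
            raise InvalidArgumentError("variability_level must be >= 0")


@dataclass
class LabeledDataset:
    """A cohort's labeled recordings plus the provenance that generated them."""

    recordings: list[Recording]
    config: SimConfig
    phenotypes: list[UserPhenotype] = field(default_factory=list)
    bank: list[GestureTemplate] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = {t.gesture_id for t in self.bank} if self.bank else None
        for rec in self.recordings:
            if rec.n_channels != self.config.n_channels:
                raise ShapeError(
                    f"recording has {rec.n_channels} channels, config says {self.config.n_channels}"
                )
            if rec.sampling_rate != self.config.sampling_rate:
                raise InvalidArgumentError("all recordings must share the config sampling rate")
            if known is not None and rec.gesture_id not in known:
                raise InvalidArgumentError(f"gesture {rec.gesture_id!r} not in the owning bank")

    def __len__(self) -> int:
        return len(self.recordings)

    def by_user(self) -> dict[str, list[Recording]]:
        out: dict[str, list[Recording]] = {}
        for rec in self.recordings:
            out.setdefault(rec.user_id, []).append(rec)
        return out


def make_gesture_bank(
    n_gestures: int,
    n_channels: int = 4,
    seed: int = 0,
    baseline_amplitude: float = 0.05,
) -> list[GestureTemplate]:
    """Sample a bank of pairwise-distinct gesture templates.

    Each gesture activates a distinct subset of channels (cycling through the
    nonempty channel subsets in a seeded order) with randomized onsets,
    durations, peaks and shapes. Distinct active-channel subsets keep the
    bank separable the way real gestures recruiting different muscles are;
    with 4 channels up to 15 gestures get unique subsets before subsets
    repeat with fresh random profiles.
    """
    if n_gestures < 1:
        raise InvalidArgumentError(f"n_gestures must be >= 1, got {n_gestures}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    subsets = [
        s
        for r in range(1, n_channels + 1)
        for s in itertools.combinations(range(n_channels), r)
    ]
    rng.shuffle(subsets)
    bank: list[GestureTemplate] = []
    seen: set[tuple] = set()
    i = 0
    while len(bank) < n_gestures:
        active = set(subsets[i % len(subsets)])
        i += 1
        profiles = []
        for c in range(n_channels):
            if c in active:
                # a cued repetition holds the gesture for most of the recording,
                # so nearly every window overlaps the activation; temporal
                # parameters are kept in a narrow band because fine hand
                # gestures share similar contraction envelopes — identity
                # lives mainly in the spatial recruitment pattern (which
                # channels activate and how strongly)
                onset = float(rng.uniform(0.02, 0.06))
                dur = float(rng.uniform(0.85, min(0.95, 1.0 - onset)))
                peak = float(rng.uniform(4.0, 8.0))
                shape = "trapezoid" if rng.random() < 0.5 else "gaussian-burst"
                profiles.append(ChannelProfile(onset, dur, peak, shape))
            else:
                profiles.append(
                    ChannelProfile(0.0, 1.0, baseline_amplitude, "trapezoid")
                )
        key = tuple((p.onset_fraction, p.duration_fraction, p.peak_amplitude, p.shape) for p in profiles)
        if key in seen:  # continuous draws collide with probability 0, but guarantee it
            continue
        seen.add(key)
        bank.append(
            GestureTemplate(
                gesture_id=f"g{len(bank):02d}",
                profiles=tuple(profiles),
                baseline_amplitude=baseline_amplitude,
            )
        )
    return bank


def sample_phenotypes(
    n_users: int,
    variability_level: float,
    seed: int = 0,
    n_channels: int = 4,
) -> list[UserPhenotype]:
    """Draw a cohort of user phenotypes.

    Every dispersion scales linearly with ``variability_level``; at level 0
    all users collapse to the identity phenotype (unit gains, identity
    mixing, zero jitter and drift, common noise floor), which is the null
    condition of the personalization experiments.
    """
    if n_users < 1:
        raise InvalidArgumentError(f"n_users must be >= 1, got {n_users}")
    if variability_level < 0:
        raise InvalidArgumentError("variability_level must be >= 0")
    v = float(variability_level)
    phenotypes = []
    for u in range(n_users):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(u,)))
        gains = np.exp(v * _GAIN_LOG_SD * rng.standard_normal(n_channels))
        # timing: a static habitual onset shift separates users; the
        # per-repetition jitter around it is small (repetitions of one user
        # are far more consistent than performances across users)
        offset = v * _TIMING_OFFSET_SD_S * float(rng.standard_normal())
        # within-user repetition consistency is a property of the person, not
        # of cohort diversity: jitter saturates instead of growing without
        # bound as the cohort is made more heterogeneous
        jitter = _JITTER_SD_S * float(np.tanh(v)) * float(rng.uniform(0.5, 1.5))
        # shift severity is itself heterogeneous: some users wear the sleeve
        # well (near-identity mixing), some badly
        eps = min(v * _MIXING_MASS * float(rng.uniform(0.0, 1.5)), _MIXING_MASS_CAP)
        # electrode shift rotates the sleeve onto neighboring muscles: the
        # off-diagonal mass goes mostly to a per-user channel permutation,
        # with a diffuse crosstalk remainder
        perm = np.eye(n_channels)[rng.permutation(n_channels)]
        diffuse = rng.dirichlet(np.ones(n_channels), size=n_channels)
        mixing = (1.0 - eps) * np.eye(n_channels) + eps * (0.75 * perm + 0.25 * diffuse)
        noise = _NOISE_BASE_MV * float(np.exp(v * _NOISE_LOG_SD * rng.standard_normal()))
        drift = v * _DRIFT_MV * float(rng.uniform(0.5, 1.5))
        phenotypes.append(
            UserPhenotype(
                user_id=f"u{u:02d}",
                gains=gains,
                timing_jitter_sd=jitter,
                channel_mixing=mixing,
                noise_sd=noise,
                drift_amplitude=drift,
                timing_offset_s=offset,
            )
        )
    return phenotypes


def synthesize_repetition(
    template: GestureTemplate,
    phenotype: UserPhenotype,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Generate one envelope recording of the gesture as performed by the user.

    Pipeline: render template profiles -> per-channel gains -> timing jitter
    -> channel mixing -> baseline drift + Gaussian noise -> clip at zero
    (an envelope is a rectified magnitude, so every sample is nonnegative).
    """
    if template.n_channels != config.n_channels or phenotype.n_channels != config.n_channels:
        raise ShapeError(
            f"channel mismatch: template={template.n_channels}, "
            f"phenotype={phenotype.n_channels}, config={config.n_channels}"
        )
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed))
    n = int(round(config.repetition_duration * config.sampling_rate))
    shift = phenotype.timing_offset_s
    if phenotype.timing_jitter_sd > 0:
        shift += float(rng.normal(0.0, phenotype.timing_jitter_sd))
    x = template.render(n, config.repetition_duration, time_shift_s=shift)
    # contraction strength varies trial to trial even within one user; the
    # common effort factor scales all channels jointly (spatial ratios are
    # preserved, absolute amplitude is not a reliable cue)
    if config.variability_level > 0:
        effort = float(np.exp(_EFFORT_LOG_SD * rng.standard_normal()))
        x = template.baseline_amplitude + (x - template.baseline_amplitude) * effort
    x = x * phenotype.gains[:, None]
    x = phenotype.channel_mixing @ x
    if phenotype.drift_amplitude > 0:
        t = np.arange(n) / config.sampling_rate
        freq = float(rng.uniform(0.05, 0.2))
        phase = float(rng.uniform(0.0, 2.0 * np.pi))
        x = x + phenotype.drift_amplitude * np.sin(2.0 * np.pi * freq * t + phase)[None, :]
    if phenotype.noise_sd > 0:
        x = x + rng.normal(0.0, phenotype.noise_sd, size=x.shape)
    x = np.clip(x, 0.0, None)
    return Recording(
        samples=x.T,
        sampling_rate=config.sampling_rate,
        user_id=phenotype.user_id,
        gesture_id=template.gesture_id,
    )


def synthesize_raw_repetition(
    template: GestureTemplate,
    phenotype: UserPhenotype,
    config: SimConfig,
    raw_rate: float = 1000.0,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Generate a raw-mode repetition: a zero-mean noise carrier amplitude-
    modulated by the envelope, at ``raw_rate`` Hz.

    Used to exercise the rectify -> low-pass -> decimate envelope emulation
    in :mod:`gesturekit.preprocessing`; the classifier itself always consumes
    envelopes.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed))
    n = int(round(config.repetition_duration * raw_rate))
    env = template.render(n, config.repetition_duration)
    env = phenotype.channel_mixing @ (env * phenotype.gains[:, None])
    # white carrier scaled so the rectified mean matches the envelope:
    # E|aZ| = a*sqrt(2/pi) for Z ~ N(0,1)
    carrier = rng.standard_normal(env.shape)
    raw = env / np.sqrt(2.0 / np.pi) * carrier
    return Recording(
        samples=raw.T,
        sampling_rate=raw_rate,
        user_id=phenotype.user_id,
        gesture_id=template.gesture_id,
    )


def synthesize_dataset(
    bank: Sequence[GestureTemplate],
    phenotypes: Sequence[UserPhenotype],
    reps_per_gesture: int,
    config: SimConfig,
    assignments: Mapping[str, Sequence[str]] | None = None,
) -> LabeledDataset:
    """Generate a full labeled cohort dataset.

    ``assignments`` maps user_id to the gesture ids that user performs
    (default: every user performs the whole bank). Each (user, gesture,
    repetition) triple gets its own random substream spawned from the config
    seed, so datasets are reproducible and repetitions independent.
    """
    if not bank:
        raise InvalidArgumentError("gesture bank is empty")
    if reps_per_gesture < 1:
        raise InvalidArgumentError(f"reps_per_gesture must be >= 1, got {reps_per_gesture}")
    by_id = {t.gesture_id: t for t in bank}
    recordings: list[Recording] = []
    for u, phen in enumerate(phenotypes):
        gesture_ids = (
            list(assignments[phen.user_id]) if assignments is not None else [t.gesture_id for t in bank]
        )
        for gid in gesture_ids:
            if gid not in by_id:
                raise InvalidArgumentError(f"assigned gesture {gid!r} not in the bank")
        for j, gid in enumerate(gesture_ids):
            for k in range(reps_per_gesture):
                rng = np.random.default_rng(
                    np.random.SeedSequence(config.rng_seed, spawn_key=(u, j, k))
                )
                recordings.append(synthesize_repetition(by_id[gid], phen, config, rng=rng))
    return LabeledDataset(
        recordings=recordings, config=config, phenotypes=list(phenotypes), bank=list(bank)
    )
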
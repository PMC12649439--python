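"""Personalized-vs-cross-user model experiments on synthetic cohorts.

Two experiment harnesses mirror the system's evaluation protocol:

* :func:`run_group_size_scan` — train, for each cohort subset size U, one
  *cross-user* model on the pooled windows of U users and U *personalized*
  models (one per user), with model architecture, per-user data budget and
  training configuration held identical between arms. The quantity of
  interest is the *gap*: mean personalized validation accuracy minus
  cross-user validation accuracy, in percentage points, as a function of U.
  With heterogeneous users the gap is expected to be positive and to grow
  with cohort size; with a zero-variability (clone) cohort it is a null
  control near zero.

* :func:`run_live_protocol` — the live study design: each of 7 synthetic
  subjects is assigned 3 random gestures from a 10-gesture bank and performs
  each 5 times; a personalized model is trained per subject and one
  cross-user model on everyone's data combined (classes = union of assigned
  gestures, so the shared model faces its real deployment task).

Both arms consume byte-identical raw window sets per user — only model
sharing differs. The personalized arm is literally the pooled arm run on a
single-user subset (one shared code path, with the model seed derived from
the sorted user tuple), so at U = 1 the two arms coincide and the gap is
exactly zero.

Accuracy is window-level validation accuracy, macro-averaged over users.
Repetition-level accuracy (majority vote over a repetition's windows) is
available from :func:`repetition_accuracy`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .errors import InvalidArgumentError
from .model import ModelArtifact, ModelConfig, TrainConfig, TrainingReport, train
from .nn import softmax_cross_entropy
from .preprocessing import ScalerParams, WindowBatch, WindowingConfig, segment_windows
from .signal_io import Recording
from .synth import (
    GestureTemplate,
    SimConfig,
    UserPhenotype,
    make_gesture_bank,
    sample_phenotypes,
    synthesize_dataset,
)

__all__ = [
    "CohortSpec",
    "EvalResult",
    "run_group_size_scan",
    "run_live_protocol",
    "summarize",
    "repetition_accuracy",
]


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic cohort's design: who performs what, how often, and how
    variable the users are. ``gestures_per_user=None`` means everyone
    performs the whole bank (the group-size-scan design)."""

    n_users: int = 12
    bank_size: int = 8
    gestures_per_user: int | None = None
    reps_per_gesture: int = 4
    variability_level: float = 1.0
    repetition_duration: float = 2.0
    n_channels: int = 4
    sampling_rate: float = 50.0
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)

    def __post_init__(self) -> None:
        if self.n_users < 1 or self.bank_size < 1:
            raise InvalidArgumentError("n_users and bank_size must be >= 1")
        if self.gestures_per_user is not None and self.gestures_per_user > self.bank_size:
            raise InvalidArgumentError("gestures_per_user cannot exceed bank_size")
        if self.reps_per_gesture < 1:
            raise InvalidArgumentError("reps_per_gesture must be >= 1")
        if not self.seeds:
            raise InvalidArgumentError("at least one seed is required")


@dataclass
class EvalResult:
    """Seed-averaged experiment outcome.

    For a scan, rows are indexed by cohort subset size; for the live
    protocol, by subject. ``gap_pp`` is mean personalized minus cross-user
    accuracy in percentage points.
    """

    kind: str  # "scan" | "live"
    index_name: str
    index: list
    personalized_acc: list[float]
    cross_acc: list[float]
    gap_pp: list[float]
    personalized_loss: list[float] = field(default_factory=list)
    cross_loss: list[float] = field(default_factory=list)
    seeds: tuple[int, ...] = ()
    per_seed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.index)
        if not (len(self.personalized_acc) == len(self.cross_acc) == len(self.gap_pp) == n):
            raise InvalidArgumentError("result series must all have one entry per index row")
        for acc in list(self.personalized_acc) + list(self.cross_acc):
            if not (0.0 <= acc <= 1.0):
                raise InvalidArgumentError(f"accuracy {acc} outside [0, 1]")

    @property
    def mean_gap_pp(self) -> float:
        return float(np.mean(self.gap_pp))

    def to_frame(self) -> pd.DataFrame:
        data = {
            self.index_name: self.index,
            "personalized_acc": self.personalized_acc,
            "cross_user_acc": self.cross_acc,
            "gap_pp": self.gap_pp,
        }
        if self.personalized_loss:
            data["personalized_loss"] = self.personalized_loss
            data["cross_user_loss"] = self.cross_loss
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# deterministic seed derivation


def _seed32(*parts) -> int:
    """Fold strings/ints into a deterministic 31-bit seed."""
    entropy = [
        int(p) if isinstance(p, (int, np.integer)) else zlib.crc32(str(p).encode())
        for p in parts
    ]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# cohort construction and per-user window splits


def _window_scaler(windows: np.ndarray) -> ScalerParams:
    """Per-channel scaler over a (n, channels, window_len) window stack."""
    return ScalerParams(
        mean=windows.mean(axis=(0, 2)), std=windows.std(axis=(0, 2), ddof=0)
    )


def _standardize(windows: np.ndarray, scaler: ScalerParams) -> np.ndarray:
    return (windows - scaler.mean[None, :, None]) / scaler.safe_std[None, :, None]


@dataclass
class _UserSplit:
    """One user's raw (unstandardized) train/validation windows, labeled in
    the union class space. Identical in both experiment arms."""

    train_w: np.ndarray
    train_y: np.ndarray
    val_w: np.ndarray
    val_y: np.ndarray
    gestures: tuple[str, ...]  # this user's own gestures, sorted


def _split_user_windows(
    recordings: Sequence[Recording],
    union_map: Mapping[str, int],
    wcfg: WindowingConfig,
    val_fraction: float,
    seed: int,
) -> _UserSplit:
    batches = [
        segment_windows(rec.samples, wcfg, label=union_map[rec.gesture_id], user_id=rec.user_id)
        for rec in recordings
    ]
    batch = WindowBatch.concatenate(batches)
    idx_tr, idx_va = train_test_split(
        np.arange(len(batch)),
        test_size=val_fraction,
        stratify=batch.labels,
        random_state=seed % (2**32),
    )
    idx_tr, idx_va = np.sort(idx_tr), np.sort(idx_va)
    gestures = tuple(sorted({rec.gesture_id for rec in recordings}))
    return _UserSplit(
        train_w=batch.windows[idx_tr],
        train_y=batch.labels[idx_tr],
        val_w=batch.windows[idx_va],
        val_y=batch.labels[idx_va],
        gestures=gestures,
    )


def _build_cohort_splits(
    spec: CohortSpec, seed: int, wcfg: WindowingConfig, val_fraction: float
) -> tuple[dict[str, _UserSplit], list[str]]:
    """Generate one cohort realization and split it per user.

    Returns (splits keyed by user_id, union class names sorted)."""
    bank = make_gesture_bank(spec.bank_size, spec.n_channels, seed=_seed32(seed, "bank"))
    phenotypes = sample_phenotypes(
        spec.n_users, spec.variability_level, seed=_seed32(seed, "phen"), n_channels=spec.n_channels
    )
    assignments = None
    if spec.gestures_per_user is not None:
        gids = [t.gesture_id for t in bank]
        assignments = {}
        for u, phen in enumerate(phenotypes):
            rng = np.random.default_rng(np.random.SeedSequence(_seed32(seed, "assign", u)))
            assignments[phen.user_id] = sorted(
                rng.choice(gids, size=spec.gestures_per_user, replace=False).tolist()
            )
    config = SimConfig(
        n_channels=spec.n_channels,
        sampling_rate=spec.sampling_rate,
        repetition_duration=spec.repetition_duration,
        variability_level=spec.variability_level,
        rng_seed=_seed32(seed, "data"),
    )
    dataset = synthesize_dataset(
        bank, phenotypes, spec.reps_per_gesture, config, assignments=assignments
    )
    union = sorted({rec.gesture_id for rec in dataset.recordings})
    union_map = {g: i for i, g in enumerate(union)}
    splits = {
        uid: _split_user_windows(
            recs, union_map, wcfg, val_fraction, _seed32(seed, "split", uid)
        )
        for uid, recs in sorted(dataset.by_user().items())
    }
    return splits, union


# ---------------------------------------------------------------------------
# the single shared training arm


def _train_pooled_arm(
    uids: Sequence[str],
    splits: Mapping[str, _UserSplit],
    class_names: Sequence[str],
    seed: int,
    tcfg: TrainConfig,
    mcfg_template: ModelConfig | None = None,
) -> tuple[ModelArtifact, TrainingReport, dict[str, float], dict[str, float]]:
    """Train one model on the pooled windows of ``uids``.

    ``class_names`` defines this arm's class space; window labels (in the
    union space) are remapped into it. Returns the artifact, the training
    report, and per-user validation accuracy and loss. The personalized arm
    is this function with a single-user ``uids``.
    """
    uids = sorted(uids)
    name_to_idx = {g: i for i, g in enumerate(class_names)}

    def remap(y: np.ndarray, gestures_by_union: Mapping[int, str]) -> np.ndarray:
        return np.array([name_to_idx[gestures_by_union[int(v)]] for v in y], dtype=int)

    # reconstruct union index -> gesture name (labels arrive in union space)
    all_union = sorted({g for s in splits.values() for g in s.gestures})
    union_lookup = {i: g for i, g in enumerate(all_union)}

    train_w = np.concatenate([splits[u].train_w for u in uids], axis=0)
    train_y = np.concatenate([remap(splits[u].train_y, union_lookup) for u in uids])
    val_w = np.concatenate([splits[u].val_w for u in uids], axis=0)
    val_y = np.concatenate([remap(splits[u].val_y, union_lookup) for u in uids])

    scaler = _window_scaler(train_w)
    mcfg = ModelConfig(
        n_channels=train_w.shape[1],
        n_classes=len(class_names),
        window_len=train_w.shape[2],
        conv_blocks=mcfg_template.conv_blocks if mcfg_template else ((32, 3, 2), (64, 3, 2)),
        dense_hidden=mcfg_template.dense_hidden if mcfg_template else (256, 128, 64, 32),
    )
    arm_seed = _seed32(seed, "model", *uids)
    arm_tcfg = TrainConfig(
        learning_rate=tcfg.learning_rate,
        batch_size=tcfg.batch_size,
        min_epochs=tcfg.min_epochs,
        max_epochs=tcfg.max_epochs,
        early_stop_patience=tcfg.early_stop_patience,
        validation_fraction=tcfg.validation_fraction,
        seed=arm_seed,
    )
    artifact, report = train(
        WindowBatch(_standardize(train_w, scaler), train_y),
        mcfg,
        arm_tcfg,
        scaler=scaler,
        gesture_map=dict(name_to_idx),
        validation=WindowBatch(_standardize(val_w, scaler), val_y),
    )
    net = artifact.network()
    acc: dict[str, float] = {}
    loss: dict[str, float] = {}
    for uid in uids:
        vw = _standardize(splits[uid].val_w, scaler)
        vy = remap(splits[uid].val_y, union_lookup)
        logits = net.forward(vw)
        l, _ = softmax_cross_entropy(logits, vy)
        acc[uid] = float(np.mean(logits.argmax(axis=1) == vy))
        loss[uid] = l
    return artifact, report, acc, loss


# ---------------------------------------------------------------------------
# experiments


def run_group_size_scan(
    cohort: CohortSpec,
    subset_sizes: Sequence[int],
    tcfg: TrainConfig | None = None,
    wcfg: WindowingConfig = WindowingConfig(),
    val_fraction: float = 0.2,
    data_provider: Callable[[int], tuple[dict[str, _UserSplit], list[str]]] | None = None,
) -> EvalResult:
    """Personalized vs cross-user accuracy as a function of cohort size.

    For each subset size U (users taken in a fixed cohort order) and each
    seed: train U personalized models and one pooled cross-user model on
    identical per-user window sets, then macro-average validation accuracy
    over the subset's users in both arms. Results are averaged over
    ``cohort.seeds``. ``data_provider`` may replace the synthetic cohort
    with externally loaded per-user splits (same return contract as the
    internal builder), enabling real-dataset plug-in.
    """
    subset_sizes = list(subset_sizes)
    if any(u < 1 for u in subset_sizes):
        raise InvalidArgumentError("subset sizes must be >= 1")
    if max(subset_sizes) > cohort.n_users:
        raise InvalidArgumentError("subset size exceeds the cohort's n_users")
    tcfg = tcfg or TrainConfig(max_epochs=40)

    per_seed: dict[int, dict] = {}
    for seed in cohort.seeds:
        builder = data_provider if data_provider is not None else (
            lambda s: _build_cohort_splits(cohort, s, wcfg, val_fraction)
        )
        splits, union = builder(seed)
        uids = sorted(splits.keys())
        # personalized models are independent of U: train once per user
        pers_acc: dict[str, float] = {}
        pers_loss: dict[str, float] = {}
        for uid in uids[: max(subset_sizes)]:
            _, _, acc, loss = _train_pooled_arm(
                [uid], splits, list(splits[uid].gestures), seed, tcfg
            )
            pers_acc[uid] = acc[uid]
            pers_loss[uid] = loss[uid]
        rows = {}
        for u_size in subset_sizes:
            subset = uids[:u_size]
            arm_classes = sorted({g for uid in subset for g in splits[uid].gestures})
            _, _, cross_acc, cross_loss = _train_pooled_arm(
                subset, splits, arm_classes, seed, tcfg
            )
            rows[u_size] = {
                "personalized": float(np.mean([pers_acc[u] for u in subset])),
                "cross": float(np.mean([cross_acc[u] for u in subset])),
                "personalized_loss": float(np.mean([pers_loss[u] for u in subset])),
                "cross_loss": float(np.mean([cross_loss[u] for u in subset])),
            }
        per_seed[seed] = rows

    pers = [float(np.mean([per_seed[s][u]["personalized"] for s in cohort.seeds])) for u in subset_sizes]
    cross = [float(np.mean([per_seed[s][u]["cross"] for s in cohort.seeds])) for u in subset_sizes]
    pers_l = [float(np.mean([per_seed[s][u]["personalized_loss"] for s in cohort.seeds])) for u in subset_sizes]
    cross_l = [float(np.mean([per_seed[s][u]["cross_loss"] for s in cohort.seeds])) for u in subset_sizes]
    return EvalResult(
        kind="scan",
        index_name="subset_size",
        index=subset_sizes,
        personalized_acc=pers,
        cross_acc=cross,
        gap_pp=[100.0 * (p - c) for p, c in zip(pers, cross)],
        personalized_loss=pers_l,
        cross_loss=cross_l,
        seeds=tuple(cohort.seeds),
        per_seed=per_seed,
    )


def run_live_protocol(
    n_subjects: int = 7,
    gestures_per_subject: int = 3,
    reps: int = 5,
    bank_size: int = 10,
    variability_level: float = 1.0,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    tcfg: TrainConfig | None = None,
    wcfg: WindowingConfig = WindowingConfig(),
    val_fraction: float = 0.2,
    repetition_duration: float = 4.0,
) -> EvalResult:
    """The live-study reproduction: per-subject gesture triplets.

    Each synthetic subject gets ``gestures_per_subject`` random gestures
    from a shared bank and performs each ``reps`` times; personalized models
    (classes = own gestures) are compared against one cross-user model
    (classes = union of everyone's gestures) on each subject's validation
    windows. Rows are subjects, averaged over seeds.
    """
    if bank_size < gestures_per_subject:
        raise InvalidArgumentError("bank must be at least as large as gestures_per_subject")
    if reps < 2:
        raise InvalidArgumentError("need reps >= 2 to hold out a validation split")
    tcfg = tcfg or TrainConfig(max_epochs=40)
    cohort = CohortSpec(
        n_users=n_subjects,
        bank_size=bank_size,
        gestures_per_user=gestures_per_subject,
        reps_per_gesture=reps,
        variability_level=variability_level,
        repetition_duration=repetition_duration,
        seeds=tuple(seeds),
    )
    per_seed: dict[int, dict] = {}
    for seed in cohort.seeds:
        splits, union = _build_cohort_splits(cohort, seed, wcfg, val_fraction)
        uids = sorted(splits.keys())
        rows = {}
        _, _, cross_acc, cross_loss = _train_pooled_arm(uids, splits, union, seed, tcfg)
        for uid in uids:
            _, _, acc, loss = _train_pooled_arm(
                [uid], splits, list(splits[uid].gestures), seed, tcfg
            )
            rows[uid] = {
                "personalized": acc[uid],
                "cross": cross_acc[uid],
                "personalized_loss": loss[uid],
                "cross_loss": cross_loss[uid],
            }
        per_seed[seed] = rows

    uids = sorted(per_seed[cohort.seeds[0]].keys())
    pers = [float(np.mean([per_seed[s][u]["personalized"] for s in cohort.seeds])) for u in uids]
    cross = [float(np.mean([per_seed[s][u]["cross"] for s in cohort.seeds])) for u in uids]
    pers_l = [float(np.mean([per_seed[s][u]["personalized_loss"] for s in cohort.seeds])) for u in uids]
    cross_l = [float(np.mean([per_seed[s][u]["cross_loss"] for s in cohort.seeds])) for u in uids]
    return EvalResult(
        kind="live",
        index_name="subject",
        index=uids,
        personalized_acc=pers,
        cross_acc=cross,
        gap_pp=[100.0 * (p - c) for p, c in zip(pers, cross)],
        personalized_loss=pers_l,
        cross_loss=cross_l,
        seeds=tuple(cohort.seeds),
        per_seed=per_seed,
    )


def summarize(result: EvalResult) -> tuple[str, dict]:
    """Render an EvalResult as a CSV table plus plot-ready series.

    Deterministic: the same result always yields identical bytes. Returns
    (csv_text, series) where ``series`` maps curve names to lists suitable
    for plotting gap vs cohort size (or per-subject bars)."""
    if not result.index:
        raise InvalidArgumentError("cannot summarize an empty result")
    frame = result.to_frame()
    csv_text = frame.to_csv(index=False, float_format="%.6f")
    series = {
        "index": list(result.index),
        "personalized_acc": list(result.personalized_acc),
        "cross_user_acc": list(result.cross_acc),
        "gap_pp": list(result.gap_pp),
    }
    return csv_text, series


def repetition_accuracy(
    artifact: ModelArtifact,
    recordings: Sequence[Recording],
    wcfg: WindowingConfig = WindowingConfig(),
) -> float:
    """Repetition-level accuracy: majority vote over each recording's
    windows (ties to the lowest class index)."""
    if not recordings:
        raise InvalidArgumentError("no recordings given")
    net = artifact.network()
    name_to_idx = artifact.gesture_map
    correct = 0
    for rec in recordings:
        x = (rec.samples - artifact.scaler.mean) / artifact.scaler.safe_std
        batch = segment_windows(x, wcfg)
        if len(batch) == 0:
            continue
        preds = net.forward(batch.windows).argmax(axis=1)
        counts = np.bincount(preds, minlength=len(name_to_idx))
        if counts.argmax() == name_to_idx[rec.gesture_id]:
            correct += 1
    return correct / len(recordings)
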
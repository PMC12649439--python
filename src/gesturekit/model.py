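"""The lightweight 1D-CNN gesture classifier.

Architecture: two Conv1D->ReLU->maxpool blocks followed by a stack of five
fully connected layers that progressively reduce the feature space down to
one logit per gesture class; the class count is set dynamically from the
user's gesture bank. Training uses Adam (lr 0.001) on softmax cross-entropy
in mini-batches of 32, runs for at least 10 epochs, and early-stops once
validation loss has gone ``patience`` epochs without improvement; the
returned artifact carries the weights of the best-validation-loss epoch.

A trained model travels as a :class:`ModelArtifact`: weights, the
gesture-to-class map, the standardization parameters fit on the training
data, and the sensor configuration, serialized to a single versioned
zip container (``meta.json`` + ``weights.npz``).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .errors import (
    ArtifactError,
    InvalidArgumentError,
    SchemaVersionError,
    ShapeError,
)
from .nn import Adam, ConvNet1D, softmax, softmax_cross_entropy
from .preprocessing import ScalerParams, WindowBatch

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainingReport",
    "ModelArtifact",
    "EarlyStopper",
    "simulate_early_stopping",
    "build_model",
    "train",
    "predict_window",
    "predict_batch",
    "save_artifact",
    "load_artifact",
]

ARTIFACT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Network shape: exactly two conv blocks and five dense layers.

    ``conv_blocks`` entries are (filters, kernel, pool); ``dense_hidden``
    gives the four hidden dense widths, the fifth (output) width being
    ``n_classes``.
    """

    n_channels: int
    n_classes: int
    window_len: int = 32
    conv_blocks: tuple[tuple[int, int, int], ...] = ((32, 3, 2), (64, 3, 2))
    dense_hidden: tuple[int, ...] = (256, 128, 64, 32)

    def __post_init__(self) -> None:
        if len(self.conv_blocks) != 2:
            raise InvalidArgumentError("exactly 2 convolutional blocks are required")
        if len(self.dense_hidden) != 4:
            raise InvalidArgumentError(
                "exactly 5 dense layers are required (4 hidden widths + output)"
            )
        if self.n_classes < 1:
            raise InvalidArgumentError("n_classes must be >= 1")
        if self.n_channels < 1 or self.window_len < 1:
            raise InvalidArgumentError("n_channels and window_len must be >= 1")
        if any(w < 1 for w in self.dense_hidden):
            raise InvalidArgumentError("dense widths must be >= 1")

    @property
    def dense_widths(self) -> tuple[int, ...]:
        return self.dense_hidden + (self.n_classes,)

    def to_dict(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "n_classes": self.n_classes,
            "window_len": self.window_len,
            "conv_blocks": [list(b) for b in self.conv_blocks],
            "dense_hidden": list(self.dense_hidden),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        return cls(
            n_channels=int(d["n_channels"]),
            n_classes=int(d["n_classes"]),
            window_len=int(d["window_len"]),
            conv_blocks=tuple(tuple(b) for b in d["conv_blocks"]),
            dense_hidden=tuple(d["dense_hidden"]),
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam at 0.001, batches of 32, min 10 epochs."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    min_epochs: int = 10
    max_epochs: int = 200
    early_stop_patience: int = 5
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_epochs > self.max_epochs:
            raise InvalidArgumentError("min_epochs must be <= max_epochs")
        if not (0.0 < self.validation_fraction < 1.0):
            raise InvalidArgumentError("validation_fraction must be in (0, 1)")
        if self.batch_size < 1 or self.early_stop_patience < 1:
            raise InvalidArgumentError("batch_size and early_stop_patience must be >= 1")


@dataclass
class TrainingReport:
    """Per-epoch loss/accuracy curves and how training stopped."""

    train_loss: list[float]
    val_loss: list[float]
    val_accuracy: list[float]
    stopped_epoch: int
    stop_reason: str  # "early_stop" | "max_epochs"
    best_epoch: int

    def __post_init__(self) -> None:
        if not (len(self.train_loss) == len(self.val_loss) == len(self.val_accuracy) == self.stopped_epoch):
            raise InvalidArgumentError("loss series length must equal stopped_epoch")

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch - 1]

    @property
    def final_val_accuracy(self) -> float:
        return self.val_accuracy[self.best_epoch - 1]

    def to_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
            "stopped_epoch": self.stopped_epoch,
            "stop_reason": self.stop_reason,
            "best_epoch": self.best_epoch,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrainingReport":
        return cls(
            train_loss=list(d["train_loss"]),
            val_loss=list(d["val_loss"]),
            val_accuracy=list(d["val_accuracy"]),
            stopped_epoch=int(d["stopped_epoch"]),
            stop_reason=str(d["stop_reason"]),
            best_epoch=int(d["best_epoch"]),
        )


class EarlyStopper:
    """Stop once validation loss has not improved for ``patience`` epochs,
    but never before ``min_epochs`` epochs have run."""

    def __init__(self, min_epochs: int, patience: int):
        self.min_epochs = min_epochs
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.since_improve = 0

    def update(self, val_loss: float, epoch: int) -> bool:
        """Record epoch ``epoch`` (1-based); return True if training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.since_improve = 0
        else:
            self.since_improve += 1
        return epoch >= self.min_epochs and self.since_improve >= self.patience


def simulate_early_stopping(
    val_losses: Sequence[float], min_epochs: int, patience: int
) -> tuple[int, str]:
    """Apply the stopping rule to a fixed loss sequence.

    Returns (stopped_epoch, stop_reason): the 1-based epoch after which
    training halts, either because patience was exhausted at or after
    ``min_epochs`` ("early_stop") or because the sequence ran out
    ("max_epochs").
    """
    stopper = EarlyStopper(min_epochs, patience)
    for epoch, loss in enumerate(val_losses, start=1):
        if stopper.update(float(loss), epoch):
            return epoch, "early_stop"
    return len(val_losses), "max_epochs"


@dataclass(eq=False)
class ModelArtifact:
    """Everything needed to deploy a trained personalized model."""

    weights: dict[str, np.ndarray]
    model_config: ModelConfig
    gesture_map: dict[str, int]  # gesture label -> class index (bijective)
    scaler: ScalerParams
    sensor_config: dict  # {"n_channels": int, "sampling_rate": float}
    schema_version: int = ARTIFACT_SCHEMA_VERSION
    created_at: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def __post_init__(self) -> None:
        indices = sorted(self.gesture_map.values())
        if indices != list(range(len(self.gesture_map))):
            raise InvalidArgumentError(
                "gesture_map must be a bijection onto [0, n_classes)"
            )
        if len(self.gesture_map) != self.model_config.n_classes:
            raise InvalidArgumentError("gesture_map size must equal n_classes")
        if self.scaler.n_channels != int(self.sensor_config["n_channels"]):
            raise InvalidArgumentError(
                "scaler channel count must match the sensor configuration"
            )

    @property
    def class_names(self) -> list[str]:
        """Gesture labels ordered by class index."""
        inv = {v: k for k, v in self.gesture_map.items()}
        return [inv[i] for i in range(len(inv))]

    def network(self) -> ConvNet1D:
        net = build_model(self.model_config, seed=0)
        net.load_state_dict(self.weights)
        return net


def build_model(cfg: ModelConfig, seed: int = 0) -> ConvNet1D:
    """Instantiate the 1D-CNN with seeded, deterministic initialization."""
    return ConvNet1D(
        n_channels=cfg.n_channels,
        window_len=cfg.window_len,
        conv_blocks=cfg.conv_blocks,
        dense_widths=cfg.dense_widths,
        seed=seed,
    )


def _evaluate(net: ConvNet1D, windows: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    logits = net.forward(windows)
    loss, _ = softmax_cross_entropy(logits, labels)
    acc = float(np.mean(logits.argmax(axis=1) == labels))
    return loss, acc


def train(
    batch: WindowBatch,
    mcfg: ModelConfig,
    tcfg: TrainConfig = TrainConfig(),
    scaler: ScalerParams | None = None,
    gesture_map: Mapping[str, int] | None = None,
    sampling_rate: float = 50.0,
    validation: WindowBatch | None = None,
) -> tuple[ModelArtifact, TrainingReport]:
    """Train the classifier on standardized windows.

    If ``validation`` is not supplied, a stratified ``validation_fraction``
    split of ``batch`` is held out, fixed across epochs. Mini-batches are
    reshuffled each epoch from a generator seeded by ``tcfg.seed``, so a
    fixed seed reproduces the loss curves bitwise. The best-validation-loss
    epoch's weights go into the returned artifact.
    """
    windows = np.asarray(batch.windows, dtype=float)
    labels = np.asarray(batch.labels, dtype=int)
    present = np.unique(labels)
    missing = sorted(set(range(mcfg.n_classes)) - set(present.tolist()))
    if missing:
        raise InvalidArgumentError(
            f"classes absent from the training data: {missing}"
        )
    if validation is None:
        counts = np.bincount(labels, minlength=mcfg.n_classes)
        if counts.min() < 2:
            raise InvalidArgumentError(
                "need >= 2 windows per class for a stratified validation split"
            )
        idx_train, idx_val = train_test_split(
            np.arange(len(labels)),
            test_size=tcfg.validation_fraction,
            stratify=labels,
            random_state=tcfg.seed % (2**32),
        )
        x_train, y_train = windows[idx_train], labels[idx_train]
        x_val, y_val = windows[idx_val], labels[idx_val]
    else:
        x_train, y_train = windows, labels
        x_val = np.asarray(validation.windows, dtype=float)
        y_val = np.asarray(validation.labels, dtype=int)

    if gesture_map is None:
        gesture_map = {f"class{i}": i for i in range(mcfg.n_classes)}
    if scaler is None:
        scaler = ScalerParams(mean=np.zeros(mcfg.n_channels), std=np.ones(mcfg.n_channels))

    net = build_model(mcfg, seed=tcfg.seed)
    opt = Adam(net.params, lr=tcfg.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(tcfg.seed, spawn_key=(1,)))
    stopper = EarlyStopper(tcfg.min_epochs, tcfg.early_stop_patience)

    train_losses: list[float] = []
    val_losses: list[float] = []
    val_accs: list[float] = []
    best_state = net.state_dict()
    stop_reason = "max_epochs"
    stopped_epoch = tcfg.max_epochs

    n = len(y_train)
    for epoch in range(1, tcfg.max_epochs + 1):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tcfg.batch_size):
            sel = order[start : start + tcfg.batch_size]
            logits, cache = net.forward(x_train[sel], want_cache=True)
            loss, dlogits = softmax_cross_entropy(logits, y_train[sel])
            grads = net.backward(cache, dlogits)
            opt.step(grads)
            epoch_loss += loss * len(sel)
        train_losses.append(epoch_loss / n)
        v_loss, v_acc = _evaluate(net, x_val, y_val)
        val_losses.append(v_loss)
        val_accs.append(v_acc)
        improved = v_loss < stopper.best
        should_stop = stopper.update(v_loss, epoch)
        if improved:
            best_state = net.state_dict()
        if should_stop:
            stop_reason = "early_stop"
            stopped_epoch = epoch
            break
    else:
        stopped_epoch = tcfg.max_epochs

    artifact = ModelArtifact(
        weights=best_state,
        model_config=mcfg,
        gesture_map=dict(gesture_map),
        scaler=scaler,
        sensor_config={"n_channels": mcfg.n_channels, "sampling_rate": sampling_rate},
    )
    report = TrainingReport(
        train_loss=train_losses,
        val_loss=val_losses,
        val_accuracy=val_accs,
        stopped_epoch=stopped_epoch,
        stop_reason=stop_reason,
        best_epoch=stopper.best_epoch,
    )
    return artifact, report


def predict_batch(artifact: ModelArtifact, windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classify standardized windows ``(n, channels, window_len)``.

    Returns (class indices, probability matrix). Ties at the argmax go to
    the lowest class index; the probability rows sum to 1. Windows are
    evaluated one at a time so the result is bitwise independent of how a
    stream is batched (streaming and batch inference agree exactly).
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim == 2:
        windows = windows[None]
    net = artifact.network()
    if len(windows) == 0:
        return np.empty(0, dtype=int), np.empty((0, net.n_classes))
    probs = np.concatenate([softmax(net.forward(w[None])) for w in windows], axis=0)
    return probs.argmax(axis=1), probs


def predict_window(artifact: ModelArtifact, window: np.ndarray) -> tuple[str, np.ndarray]:
    """Classify one standardized window ``(channels, window_len)``.

    Returns the gesture label and the softmax probability vector. Pure
    function: identical windows give identical outputs.
    """
    window = np.asarray(window, dtype=float)
    mc = artifact.model_config
    if window.shape != (mc.n_channels, mc.window_len):
        raise ShapeError(
            f"expected window ({mc.n_channels}, {mc.window_len}), got {window.shape}"
        )
    idx, probs = predict_batch(artifact, window[None])
    return artifact.class_names[int(idx[0])], probs[0]


def save_artifact(artifact: ModelArtifact, destination) -> None:
    """Serialize to a single-file versioned zip: meta.json + weights.npz."""
    meta = {
        "format": "gesturekit-model",
        "schema_version": artifact.schema_version,
        "created_at": artifact.created_at,
        "model_config": artifact.model_config.to_dict(),
        "gesture_map": artifact.gesture_map,
        "scaler": artifact.scaler.to_dict(),
        "sensor_config": artifact.sensor_config,
    }
    buf = io.BytesIO()
    np.savez(buf, **artifact.weights)
    with zipfile.ZipFile(destination, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1, sort_keys=True))
        zf.writestr("weights.npz", buf.getvalue())


def load_artifact(source) -> ModelArtifact:
    """Load an artifact; schema mismatches and corrupt files raise, never
    silently misload."""
    try:
        with zipfile.ZipFile(source, "r") as zf:
            meta = json.loads(zf.read("meta.json"))
            with np.load(io.BytesIO(zf.read("weights.npz"))) as npz:
                weights = {k: npz[k] for k in npz.files}
    except (zipfile.BadZipFile, KeyError, OSError, json.JSONDecodeError, ValueError) as exc:
        raise ArtifactError(f"cannot read model artifact: {exc}") from exc
    if meta.get("format") != "gesturekit-model":
        raise ArtifactError("not a gesturekit model artifact")
    if int(meta.get("schema_version", -1)) != ARTIFACT_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"artifact schema version {meta.get('schema_version')} is not supported "
            f"(this package reads version {ARTIFACT_SCHEMA_VERSION})"
        )
    return ModelArtifact(
        weights=weights,
        model_config=ModelConfig.from_dict(meta["model_config"]),
        gesture_map={str(k): int(v) for k, v in meta["gesture_map"].items()},
        scaler=ScalerParams.from_dict(meta["scaler"]),
        sensor_config=meta["sensor_config"],
        schema_version=int(meta["schema_version"]),
        created_at=meta.get("created_at", ""),
    )
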
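"""File-backed per-user profile and model store.

The deployment database is realized as a directory tree — desk-scale,
dependency-free and diff-able. One directory per (user, life_stage) holds
append-only profile revisions, versioned model artifacts with their
training reports, staleness markers, and a prediction log:

::

    <root>/users/<user_id>/<life_stage>/
        revisions/rev_00001.json      profile revisions (append-only)
        artifacts/v00001.gkm          model artifact (zip container)
        artifacts/v00001.meta.json    training report + profile revision
        artifacts/v00001.stale        staleness marker (present = stale)
        predictions.jsonl             append-only prediction log

A *life stage* is an ordered version label for the same user (physiology
changes over a lifetime; each stage gets its own gesture bank and models).
Class indices are assigned by sorted gesture-name order so they are
deterministic across machines. Editing a gesture bank never deletes
artifacts; artifacts whose gesture map no longer matches the bank are
marked stale and excluded from ``latest_artifact``.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import (
    ConflictError,
    IntegrityError,
    InvalidArgumentError,
    NoUsableModelError,
    NotFoundError,
)
from .model import ModelArtifact, TrainingReport, load_artifact, save_artifact

__all__ = ["UserProfile", "PredictionLogEntry", "Registry"]


def _class_map(gestures: Sequence[str]) -> dict[str, int]:
    return {name: i for i, name in enumerate(sorted(gestures))}


@dataclass(frozen=True)
class UserProfile:
    """One revision of a user's gesture bank and sensor configuration."""

    user_id: str
    life_stage: str
    revision: int
    gesture_bank: tuple[str, ...]
    sensor_config: dict
    created_at: float

    def __post_init__(self) -> None:
        if len(set(self.gesture_bank)) != len(self.gesture_bank):
            raise InvalidArgumentError("gesture names must be unique within a bank")

    @property
    def class_map(self) -> dict[str, int]:
        """Gesture label -> class index, assigned by sorted name order."""
        return _class_map(self.gesture_bank)

    @property
    def trainable(self) -> bool:
        """False for a profile with an empty gesture bank."""
        return len(self.gesture_bank) > 0

    def to_dict(self) -> dict:
        return {
            "user_id": self.user_id,
            "life_stage": self.life_stage,
            "revision": self.revision,
            "gesture_bank": list(self.gesture_bank),
            "class_map": self.class_map,
            "sensor_config": self.sensor_config,
            "created_at": self.created_at,
            "trainable": self.trainable,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UserProfile":
        return cls(
            user_id=d["user_id"],
            life_stage=d["life_stage"],
            revision=int(d["revision"]),
            gesture_bank=tuple(d["gesture_bank"]),
            sensor_config=d["sensor_config"],
            created_at=float(d["created_at"]),
        )


@dataclass(frozen=True)
class PredictionLogEntry:
    """One logged streaming prediction, tied to the artifact that made it."""

    user_id: str
    timestamp_ms: int
    gesture: str
    probabilities: tuple[float, ...]
    artifact_version: int

    def to_dict(self) -> dict:
        return {
            "user_id": self.user_id,
            "timestamp_ms": self.timestamp_ms,
            "gesture": self.gesture,
            "probabilities": list(self.probabilities),
            "artifact_version": self.artifact_version,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionLogEntry":
        return cls(
            user_id=d["user_id"],
            timestamp_ms=int(d["timestamp_ms"]),
            gesture=d["gesture"],
            probabilities=tuple(d["probabilities"]),
            artifact_version=int(d["artifact_version"]),
        )


class Registry:
    """Append-only, fully on-disk store; no in-memory cache, so independent
    processes reading the same root always agree."""

    def __init__(self, root) -> None:
        self.root = Path(root)
        (self.root / "users").mkdir(parents=True, exist_ok=True)

    # ---- paths --------------------------------------------------------------

    def _stage_dir(self, user_id: str, life_stage: str) -> Path:
        return self.root / "users" / user_id / life_stage

    def _revision_paths(self, user_id: str, life_stage: str) -> list[Path]:
        d = self._stage_dir(user_id, life_stage) / "revisions"
        return sorted(d.glob("rev_*.json")) if d.is_dir() else []

    def _artifact_versions(self, user_id: str, life_stage: str) -> list[int]:
        d = self._stage_dir(user_id, life_stage) / "artifacts"
        return sorted(int(p.stem[1:]) for p in d.glob("v*.gkm")) if d.is_dir() else []

    # ---- profiles -----------------------------------------------------------

    def create_profile(
        self,
        user_id: str,
        life_stage: str,
        gestures: Sequence[str],
        sensor_config: dict | None = None,
    ) -> UserProfile:
        """Create revision 1 of a new (user, life_stage) profile."""
        stage = self._stage_dir(user_id, life_stage)
        if stage.exists():
            raise ConflictError(f"profile ({user_id!r}, {life_stage!r}) already exists")
        profile = UserProfile(
            user_id=user_id,
            life_stage=life_stage,
            revision=1,
            gesture_bank=tuple(gestures),
            sensor_config=sensor_config or {"n_channels": 4, "sampling_rate": 50.0},
            created_at=time.time(),
        )
        (stage / "revisions").mkdir(parents=True)
        (stage / "artifacts").mkdir()
        self._write_revision(profile)
        return profile

    def _write_revision(self, profile: UserProfile) -> None:
        path = (
            self._stage_dir(profile.user_id, profile.life_stage)
            / "revisions"
            / f"rev_{profile.revision:05d}.json"
        )
        path.write_text(json.dumps(profile.to_dict(), indent=1, sort_keys=True))

    def get_profile(self, user_id: str, life_stage: str) -> UserProfile:
        """Latest revision of the profile."""
        revs = self._revision_paths(user_id, life_stage)
        if not revs:
            raise NotFoundError(f"no profile for ({user_id!r}, {life_stage!r})")
        return UserProfile.from_dict(json.loads(revs[-1].read_text()))

    def list_profiles(self) -> list[tuple[str, str]]:
        out = []
        users_dir = self.root / "users"
        for user_dir in sorted(users_dir.iterdir()) if users_dir.is_dir() else []:
            for stage_dir in sorted(p for p in user_dir.iterdir() if p.is_dir()):
                out.append((user_dir.name, stage_dir.name))
        return out

    def edit_gesture_bank(
        self,
        user_id: str,
        life_stage: str,
        add: Sequence[str] = (),
        remove: Sequence[str] = (),
    ) -> UserProfile:
        """Create a new profile revision with an edited bank.

        A no-op edit returns the current revision untouched. Otherwise any
        stored artifact whose gesture map no longer matches the new bank is
        marked stale (never deleted, never silently reused).
        """
        profile = self.get_profile(user_id, life_stage)
        bank = list(profile.gesture_bank)
        for name in remove:
            if name not in bank:
                raise NotFoundError(f"cannot remove unknown gesture {name!r}")
        for name in add:
            if name in bank and name not in remove:
                raise ConflictError(f"gesture {name!r} already in the bank")
        if not add and not remove:
            return profile
        bank = [g for g in bank if g not in set(remove)] + list(add)
        new_profile = UserProfile(
            user_id=user_id,
            life_stage=life_stage,
            revision=profile.revision + 1,
            gesture_bank=tuple(bank),
            sensor_config=profile.sensor_config,
            created_at=time.time(),
        )
        self._write_revision(new_profile)
        new_map = new_profile.class_map
        for version in self._artifact_versions(user_id, life_stage):
            meta = self._artifact_meta(user_id, life_stage, version)
            if meta["gesture_map"] != new_map:
                self._mark_stale(user_id, life_stage, version)
        return new_profile

    # ---- artifacts ----------------------------------------------------------

    def _artifact_meta(self, user_id: str, life_stage: str, version: int) -> dict:
        path = self._stage_dir(user_id, life_stage) / "artifacts" / f"v{version:05d}.meta.json"
        return json.loads(path.read_text())

    def _stale_marker(self, user_id: str, life_stage: str, version: int) -> Path:
        return self._stage_dir(user_id, life_stage) / "artifacts" / f"v{version:05d}.stale"

    def _mark_stale(self, user_id: str, life_stage: str, version: int) -> None:
        self._stale_marker(user_id, life_stage, version).write_text(
            json.dumps({"marked_at": time.time()})
        )

    def is_stale(self, user_id: str, life_stage: str, version: int) -> bool:
        return self._stale_marker(user_id, life_stage, version).exists()

    def store_artifact(
        self,
        user_id: str,
        life_stage: str,
        artifact: ModelArtifact,
        report: TrainingReport | None = None,
    ) -> int:
        """Append a new artifact version; returns the version number."""
        profile = self.get_profile(user_id, life_stage)
        if artifact.gesture_map != profile.class_map:
            raise IntegrityError(
                f"artifact gesture map {artifact.gesture_map} does not match "
                f"profile bank map {profile.class_map}"
            )
        versions = self._artifact_versions(user_id, life_stage)
        version = (versions[-1] + 1) if versions else 1
        adir = self._stage_dir(user_id, life_stage) / "artifacts"
        save_artifact(artifact, adir / f"v{version:05d}.gkm")
        meta = {
            "version": version,
            "profile_revision": profile.revision,
            "gesture_map": artifact.gesture_map,
            "created_at": time.time(),
            "training_report": report.to_dict() if report is not None else None,
        }
        (adir / f"v{version:05d}.meta.json").write_text(
            json.dumps(meta, indent=1, sort_keys=True)
        )
        return version

    def latest_artifact(self, user_id: str, life_stage: str) -> tuple[ModelArtifact, int]:
        """Highest-version non-stale artifact, with its version number."""
        if not self._stage_dir(user_id, life_stage).exists():
            raise NotFoundError(f"no profile for ({user_id!r}, {life_stage!r})")
        versions = self._artifact_versions(user_id, life_stage)
        if not versions:
            raise NotFoundError(f"no artifacts stored for ({user_id!r}, {life_stage!r})")
        for version in reversed(versions):
            if not self.is_stale(user_id, life_stage, version):
                adir = self._stage_dir(user_id, life_stage) / "artifacts"
                return load_artifact(adir / f"v{version:05d}.gkm"), version
        raise NoUsableModelError(
            f"every artifact for ({user_id!r}, {life_stage!r}) is stale; retrain"
        )

    def get_training_report(
        self, user_id: str, life_stage: str, version: int
    ) -> TrainingReport | None:
        meta = self._artifact_meta(user_id, life_stage, version)
        rep = meta.get("training_report")
        return TrainingReport.from_dict(rep) if rep else None

    # ---- prediction log -----------------------------------------------------

    def log_prediction(self, life_stage: str, entry: PredictionLogEntry) -> None:
        """Append a prediction; the referenced artifact version must exist."""
        if entry.artifact_version not in self._artifact_versions(entry.user_id, life_stage):
            raise IntegrityError(
                f"prediction references unknown artifact version {entry.artifact_version}"
            )
        path = self._stage_dir(entry.user_id, life_stage) / "predictions.jsonl"
        with open(path, "a") as fh:
            fh.write(json.dumps(entry.to_dict()) + "\n")

    def query_predictions(
        self,
        user_id: str,
        life_stage: str,
        start_ms: int | None = None,
        end_ms: int | None = None,
    ) -> list[PredictionLogEntry]:
        """Logged predictions in ``[start_ms, end_ms]``, timestamp-ordered."""
        path = self._stage_dir(user_id, life_stage) / "predictions.jsonl"
        if not path.exists():
            return []
        entries = [
            PredictionLogEntry.from_dict(json.loads(line))
            for line in path.read_text().splitlines()
            if line.strip()
        ]
        if start_ms is not None:
            entries = [e for e in entries if e.timestamp_ms >= start_ms]
        if end_ms is not None:
            entries = [e for e in entries if e.timestamp_ms <= end_ms]
        return sorted(entries, key=lambda e: e.timestamp_ms)

    # ---- audit --------------------------------------------------------------

    def audit(self) -> list[str]:
        """Store-wide referential-integrity check; returns violations (empty
        list = clean store)."""
        violations: list[str] = []
        for user_id, life_stage in self.list_profiles():
            revisions = {
                json.loads(p.read_text())["revision"]
                for p in self._revision_paths(user_id, life_stage)
            }
            if not revisions:
                violations.append(f"{user_id}/{life_stage}: no profile revisions")
                continue
            versions = self._artifact_versions(user_id, life_stage)
            for version in versions:
                try:
                    meta = self._artifact_meta(user_id, life_stage, version)
                except (OSError, json.JSONDecodeError):
                    violations.append(
                        f"{user_id}/{life_stage}: artifact v{version} has no readable metadata"
                    )
                    continue
                if meta.get("profile_revision") not in revisions:
                    violations.append(
                        f"{user_id}/{life_stage}: artifact v{version} references "
                        f"missing profile revision {meta.get('profile_revision')}"
                    )
            known = set(versions)
            for entry in self.query_predictions(user_id, life_stage):
                if entry.artifact_version not in known:
                    violations.append(
                        f"{user_id}/{life_stage}: logged prediction references "
                        f"unknown artifact version {entry.artifact_version}"
                    )
        return violations
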
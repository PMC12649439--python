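"""Exception hierarchy for gesturekit.

Every error raised by the package derives from :class:`GestureKitError` so
callers can catch the whole family; the subclasses mirror the distinct
failure contracts (bad arguments, shape mismatches, parse failures with line
numbers, registry integrity, artifact schema versioning, haptic codec
failures).
"""

from __future__ import annotations


class GestureKitError(Exception):
    """Base class for all gesturekit errors."""


class InvalidArgumentError(GestureKitError, ValueError):
    """A function argument violates its documented precondition."""


class ShapeError(GestureKitError, ValueError):
    """Array / channel-count shape mismatch; message names expected and actual."""


class ParseError(GestureKitError):
    """A file could not be parsed; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigurationError(GestureKitError):
    """A model or pipeline configuration is internally inconsistent."""


class ConflictError(GestureKitError):
    """A registry key (user_id, life_stage) already exists."""


class NotFoundError(GestureKitError):
    """A requested registry entity does not exist."""


class IntegrityError(GestureKitError):
    """A registry referential-integrity constraint would be violated."""


class NoUsableModelError(GestureKitError):
    """Every stored artifact for the profile is stale."""


class ArtifactError(GestureKitError):
    """A model artifact file is unreadable or structurally invalid."""


class SchemaVersionError(ArtifactError):
    """The artifact's schema version is not supported by this package version."""


class CapacityError(GestureKitError):
    """A haptic encoding style cannot supply enough distinct patterns."""


class DecodeError(GestureKitError):
    """A haptic pattern could not be segmented; carries the failing offset in ms."""

    def __init__(self, message: str, offset_ms: int | None = None):
        self.offset_ms = offset_ms
        if offset_ms is not None:
            message = f"at offset {offset_ms} ms: {message}"
        super().__init__(message)
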
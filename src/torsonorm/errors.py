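"""Exception hierarchy for the torsonorm pipeline.

Every stage raises a subclass of :class:`TorsonormError` so callers (and the
CLI) can attach the failing stage name without string-matching messages.
"""


class TorsonormError(Exception):
    """Base class for all torsonorm errors."""


class ValidationError(TorsonormError, ValueError):
    """Invalid input data or parameters (preconditions, invariants)."""


class VolumeFormatError(TorsonormError, ValueError):
    """A volume file exists but is not a usable 3D image."""


class ModelFormatError(TorsonormError, ValueError):
    """A persisted normal-model archive is incompatible or corrupt."""


class EmptyBodyError(TorsonormError, RuntimeError):
    """No body region found above the SUV threshold."""


class OrganNotFoundError(TorsonormError, RuntimeError):
    """A rule-based organ extractor found no candidate region."""

    def __init__(self, organ: str, message: str = ""):
        self.organ = organ
        super().__init__(message or f"{organ} not found")


class DetectionError(TorsonormError, RuntimeError):
    """A plane/landmark detector could not produce an answer."""


class SolverError(TorsonormError, RuntimeError):
    """A numerical solve failed (e.g. degenerate TPS anchor configuration)."""


class StageError(TorsonormError, RuntimeError):
    """Wraps an error from a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
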
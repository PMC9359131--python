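"""Exception hierarchy shared across the package."""


class PlanScoreError(Exception):
    """Base class for all package errors."""


class ValidationError(PlanScoreError, ValueError):
    """An input violates a documented precondition or invariant."""


class GeometryError(ValidationError):
    """A structure does not fit inside the dose grid."""


class AlignmentError(ValidationError):
    """A mask and a dose grid do not share the same voxel lattice."""


class ConfigurationError(PlanScoreError, KeyError):
    """A required configuration cell (metric, parameter, path) is missing."""


class ScoringError(PlanScoreError):
    """A cohort cannot be scored (missing cell, malformed table)."""


class ScoringUndefinedError(ScoringError, ZeroDivisionError):
    """The relative-deviation score is undefined (reference value is zero)."""


class InsufficientDataError(PlanScoreError):
    """Too few observations for the requested statistical test."""


class PipelineError(PlanScoreError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
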
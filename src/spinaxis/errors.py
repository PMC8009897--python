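"""Typed exceptions raised across the pipeline.

Every error the stage modules raise derives from :class:`SpinaxisError`, so
callers (and the pipeline orchestrator) can distinguish domain failures from
programming errors.
"""


class SpinaxisError(Exception):
    """Base class for all spinaxis domain errors."""


class ValidationError(SpinaxisError, ValueError):
    """Invalid input: violated precondition or malformed specification."""


class ConstantImageError(SpinaxisError):
    """No threshold can separate classes in a constant image."""


class NoColumnError(SpinaxisError):
    """Thresholding and component selection found no spinal column."""


class AnnihilationError(SpinaxisError):
    """Erosion removed the object entirely (thinner than the element)."""


class ColumnTooShortError(SpinaxisError):
    """The boundary spans too few rows to define a medial axis."""


class UndefinedKappaError(SpinaxisError):
    """Expected agreement is 1, so chance-corrected agreement is undefined."""


class StageError(SpinaxisError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"{stage}: {cause}")
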
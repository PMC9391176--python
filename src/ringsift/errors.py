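"""Exception hierarchy for the matching / reconstruction pipeline.

Every stage failure carries the stage name so CLI reports and callers can
say *where* a pipeline died, not just that it died.
"""


class RingSiftError(Exception):
    """Base class for all package errors."""


class InputError(RingSiftError):
    """Unreadable, missing, or malformed input (names the offending path/value)."""


class ParameterError(RingSiftError):
    """A configuration value violates its contract (names the field)."""


class DegenerateSampleError(RingSiftError):
    """A minimal sample is geometrically degenerate (e.g. collinear triple)."""


class RansacFailureError(RingSiftError):
    """RANSAC could not produce a consensus model.

    ``reason`` distinguishes "too few matches" (input smaller than the
    minimum usable size) from "no consensus" (enough input, no model found).
    """

    def __init__(self, message: str, reason: str):
        super().__init__(message)
        self.reason = reason


class LowParallaxError(RingSiftError):
    """Two-view geometry is degenerate: baseline/parallax too small."""


class StageError(RingSiftError):
    """Wraps a failure with the pipeline stage in which it occurred."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
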
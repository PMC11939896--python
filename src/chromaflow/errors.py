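"""Exception hierarchy.

Every failure mode the pipeline can signal maps to one class here, so the
CLI can translate exceptions into its documented exit codes and tests can
assert on error categories rather than message strings.
"""


class ChromaflowError(Exception):
    """Base class for all package errors."""


class FormatError(ChromaflowError):
    """Input data is structurally wrong (channel count, corrupt store file)."""


class ParameterError(ChromaflowError, ValueError):
    """A parameter violates its documented precondition."""


class BoundsError(ChromaflowError):
    """A requested region does not fit inside the available extent."""


class DegenerateImageError(ChromaflowError):
    """An image is unusable for photometry (e.g. a channel with zero mean)."""


class DegenerateBlankError(ChromaflowError):
    """The blank reference has a zero channel; normalization is undefined."""


class CalibrationFailureError(ChromaflowError):
    """Calibration could not produce a positive slope/factor."""


class WaterCheckError(ChromaflowError):
    """The water zero-check failed; the session must not proceed."""


class MustCalibrateError(ChromaflowError):
    """No valid calibration state exists for the requested assay."""
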
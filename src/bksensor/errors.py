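"""Exception hierarchy shared across the package."""

from __future__ import annotations


class BKSensorError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(BKSensorError, ValueError):
    """An input violates a documented precondition."""


class FormatError(BKSensorError, ValueError):
    """A file or table does not match the documented dialect."""


class FitFailureError(BKSensorError, RuntimeError):
    """A curve fit failed to converge or produced an inadmissible result.

    ``last_iterate`` holds the final parameter vector of the optimizer,
    when one is available, to aid diagnosis.
    """

    def __init__(self, message: str, last_iterate=None, diagnostics: dict | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.diagnostics = diagnostics or {}


class NumericalFailureError(BKSensorError, RuntimeError):
    """A linear-algebra or propagation step failed beyond tolerance."""


class DegenerateInputError(BKSensorError, ValueError):
    """The data contain no usable signal for the requested analysis."""


class IllConditionedError(BKSensorError, RuntimeError):
    """The requested quantity is not recoverable from the given operating point."""


class ReconstructionQualityError(BKSensorError, RuntimeError):
    """Too many reconstruction steps were flagged; the partial result is attached."""

    def __init__(self, message: str, result=None):
        super().__init__(message)
        self.result = result
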
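"""Exception hierarchy shared across the package.

All validation failures raise subclasses of :class:`OligonoError` so callers
(and the CLI) can distinguish bad inputs (exit code 2) from numerical
failures (exit code 3).
"""


class OligonoError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(OligonoError, ValueError):
    """A scalar parameter violates its physical or mathematical domain."""


class ShapeMismatchError(OligonoError, ValueError):
    """Two arrays that must share a shape do not."""


class ChannelLookupError(OligonoError, KeyError):
    """A named channel does not exist in the stack."""


class GeometryError(OligonoError, ValueError):
    """A geometric constraint (fields on a coverslip, objects in a frame) fails."""


class GenerationError(OligonoError, RuntimeError):
    """The synthetic-data generator could not realize the requested scene."""


class NumericalFailureError(OligonoError, RuntimeError):
    """The ODE solver failed; carries solver diagnostics in ``diagnostics``."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class OutOfRangeError(OligonoError, ValueError):
    """A query time lies outside the simulated span."""


class UndefinedSummaryError(OligonoError, ValueError):
    """A summary statistic is undefined for the given (empty) input."""
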
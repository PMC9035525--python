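"""Exception hierarchy for the perictal package."""


class PerictalError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PerictalError, ValueError):
    """An argument is outside its admissible range."""


class ValidationError(PerictalError, ValueError):
    """A domain object violates one of its invariants."""


class FormatError(PerictalError, IOError):
    """An on-disk file does not conform to the expected format."""


class InsufficientDataError(PerictalError, ValueError):
    """Not enough data to run the requested operation."""


class DegenerateInputError(PerictalError, ValueError):
    """Input is degenerate (e.g. zero-power baseline)."""


class FitError(PerictalError, RuntimeError):
    """A model fit failed (rank deficiency, instability at all orders)."""


class CalibrationError(PerictalError, RuntimeError):
    """Closed-loop calibration failed to reach its target."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class DesignError(PerictalError, ValueError):
    """A factorial design is incomplete (empty cells)."""
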
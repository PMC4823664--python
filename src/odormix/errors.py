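"""Exception hierarchy for odormix."""


class OdormixError(Exception):
    """Base class for all odormix errors."""


class ValidationError(OdormixError, ValueError):
    """Invalid parameters, configuration or input data."""


class DomainError(OdormixError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class FitError(OdormixError, RuntimeError):
    """Curve fitting failed to converge or the data are degenerate."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NotRepresentableError(OdormixError, ValueError):
    """A target response cannot be written as a positive combination.

    Carries the offending coefficients and, for multi-neuron synthesis,
    the index of the neuron whose target is infeasible.
    """

    def __init__(self, message, coefficients=None, osn=None):
        super().__init__(message)
        self.coefficients = coefficients
        self.osn = osn
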
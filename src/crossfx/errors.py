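"""Exception hierarchy for crossfx."""


class CrossfxError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CrossfxError):
    """A required column or field is missing or malformed."""


class ConsistencyError(CrossfxError):
    """Input data violate a structural invariant of the crossover model."""


class DegenerateDataError(CrossfxError):
    """Data are structurally valid but carry no information for the request."""


class IdentifiabilityError(CrossfxError):
    """A parameter cannot be estimated from the data provided."""


class ConvergenceError(CrossfxError):
    """An iterative fit failed to converge.

    Carries the optimiser trace in ``history`` when available.
    """

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history


class CalibrationError(CrossfxError):
    """A simulation scenario cannot be calibrated as requested."""
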
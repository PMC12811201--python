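"""Exception hierarchy shared across the package."""


class GateopenerError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedCutoffError(GateopenerError, ValueError):
    """A hemoglobin cutoff outside the packaged characteristics table was requested."""


class DegenerateCountsError(GateopenerError, ValueError):
    """Group counts leave a zero-sized subgroup denominator in the decomposition."""


class ParameterValidationError(GateopenerError, ValueError):
    """A natural-history parameter set violates its probabilistic constraints."""


class ConfigurationError(GateopenerError, ValueError):
    """A scenario or strategy configuration is incomplete or inconsistent."""


class ContractViolationError(GateopenerError, ValueError):
    """An operation was called with a state outside its admissible domain."""


class ComparisonError(GateopenerError, ValueError):
    """Two cohort arms with mismatched scenario metadata were compared."""


class MissingReferenceError(GateopenerError, ValueError):
    """A league table was requested without any comparator reference arm."""


class CalibrationError(GateopenerError, RuntimeError):
    """Hemoglobin-distribution calibration failed to reach its target tolerance."""

    def __init__(self, message: str, deviations=None):
        super().__init__(message)
        self.deviations = deviations
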
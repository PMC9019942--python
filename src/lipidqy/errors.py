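"""Exception hierarchy for lipidqy."""


class LipidqyError(Exception):
    """Base class for all package-specific errors."""


class SpectrumValidationError(LipidqyError, ValueError):
    """Raised when a wavelength/intensity table violates spectrum invariants."""


class DomainError(LipidqyError, ValueError):
    """Raised when a scalar argument is outside its physical domain."""


class ConfigurationError(LipidqyError, ValueError):
    """Raised for invalid reference-standard or session configuration."""


class UndefinedRatioError(LipidqyError, ZeroDivisionError):
    """Raised when the comparative quantum-yield ratio is undefined (zero absorbed fraction)."""


class InsufficientDataError(LipidqyError, ValueError):
    """Raised when too few points are supplied for a fit or test."""


class DegenerateDesignError(LipidqyError, ValueError):
    """Raised when a regression design has zero variance in the predictor."""


class NonInvertibleCurveError(LipidqyError, ValueError):
    """Raised when a standard curve with zero slope is used for estimation."""


class IncomparableCurvesError(LipidqyError, ValueError):
    """Raised when two standard curves built on different parameters are compared."""


class UndefinedStatisticError(LipidqyError, ValueError):
    """Raised when a test statistic is undefined (e.g. zero variance everywhere)."""
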
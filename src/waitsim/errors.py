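"""Exception hierarchy shared across the package."""


class WaitsimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(WaitsimError, ValueError):
    """A parameter value is outside its documented domain.

    The message always names the offending field.
    """


class DomainError(WaitsimError, ValueError):
    """A function argument is outside its mathematical domain."""


class InfiniteHazardError(DomainError):
    """A 12-week risk of 1.0 implies an unbounded hazard rate."""


class InfeasibleSchemeError(WaitsimError, ValueError):
    """The budget constraint forces a non-positive low-risk wait."""


class UndefinedRelativeRiskError(WaitsimError, ZeroDivisionError):
    """Relative risk against a zero reference value."""


class EmptySelectionError(WaitsimError, LookupError):
    """No grid row satisfies the benchmark-selection constraints."""


class CalibrationError(WaitsimError, RuntimeError):
    """Calibration failed to converge or a target is unreachable."""


class MissingInputError(WaitsimError, FileNotFoundError):
    """A pipeline stage requires an output file from an earlier stage."""
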
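"""Exception hierarchy.

CLI exit-code mapping: ParameterError/ConfigError -> 2, DataError -> 3,
IntegrationError and other numerical failures -> 4.
"""


class ReplisenError(Exception):
    """Base class for all package errors."""


class ParameterError(ReplisenError, ValueError):
    """Invalid model, marker, or configuration parameter."""


class ConfigError(ParameterError):
    """Malformed configuration file or infeasible optimiser settings."""


class DataError(ReplisenError, ValueError):
    """Malformed or out-of-range observational data."""


class IntegrationError(ReplisenError, RuntimeError):
    """ODE integration failed (non-finite state or solver abort)."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class NoPeakError(ReplisenError, RuntimeError):
    """The growth-arrested fraction has no interior maximum in the window."""


class ThresholdNotReachedError(ReplisenError, RuntimeError):
    """Senescent fraction never reached the threshold within the horizon.

    Carries the fraction attained at the end of the horizon.
    """

    def __init__(self, message: str, final_fraction: float):
        super().__init__(message)
        self.final_fraction = final_fraction
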
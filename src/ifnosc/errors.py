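"""Exception hierarchy for the ifnosc package."""


class IfnoscError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(IfnoscError, ValueError):
    """A kinetic parameter violates its invariant (e.g. negative rate)."""


class InvalidStateError(IfnoscError, ValueError):
    """A model state violates its invariant (e.g. negative copy number)."""


class UsageError(IfnoscError, ValueError):
    """A caller-facing misuse (unknown name, malformed input)."""


class IntegrationFailureError(IfnoscError, RuntimeError):
    """The ODE solver failed to advance the solution.

    Attributes
    ----------
    last_good_time : float or None
        Last time point (minutes) up to which the integration succeeded.
    """

    def __init__(self, message, last_good_time=None):
        super().__init__(message)
        self.last_good_time = last_good_time


class SteadyStateError(IfnoscError, RuntimeError):
    """No steady state found after all Newton starts."""


class FitFailureError(IfnoscError, RuntimeError):
    """All optimisation starts of a parameter fit failed."""


class ConfigError(UsageError):
    """A configuration file or override is invalid."""


class ParseError(IfnoscError, ValueError):
    """A CSV file does not conform to the trajectory schema.

    Attributes
    ----------
    line : int or None
        1-based line number of the first offending record, when known.
    """

    def __init__(self, message, line=None):
        super().__init__(message)
        self.line = line
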
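"""Exception types shared across the pipeline."""


class NeckDecError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(NeckDecError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(NeckDecError):
    """A trace is too short for the requested spectral operation."""


class ConfigurationError(NeckDecError):
    """A configuration object is inconsistent (e.g. an empty frequency band)."""


class FormatError(NeckDecError):
    """A file does not conform to the expected on-disk schema."""


class SimulationDivergenceError(NeckDecError):
    """The closed-loop integration produced a non-finite or unbounded state.

    Attributes
    ----------
    time : float
        Simulation time (s) at which the state first blew up.
    """

    def __init__(self, time: float, message: str | None = None):
        self.time = time
        super().__init__(message or f"simulation diverged at t = {time:.3f} s")


class FitFailureError(NeckDecError):
    """Every restart of the parameter search ended with a non-finite score."""
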
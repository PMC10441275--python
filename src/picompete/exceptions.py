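"""Exception hierarchy for picompete."""


class PicompeteError(Exception):
    """Base class for all package errors."""


class ParameterError(PicompeteError, ValueError):
    """A kinetic or community parameter violates its constraints."""


class StateError(PicompeteError, ValueError):
    """A model state (abundance or concentration) violates its constraints."""


class IntegrationError(PicompeteError, RuntimeError):
    """Time integration failed; carries the last valid state reached."""

    def __init__(self, message, last_time=None, last_state=None):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


class DegenerateSystemError(PicompeteError, RuntimeError):
    """The steady-state system is singular (e.g. identical genera)."""


class ConfigurationError(PicompeteError, ValueError):
    """A run configuration (fit settings, design, config file) is invalid."""


class DataError(PicompeteError, ValueError):
    """An input dataset violates the incubation schema."""
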
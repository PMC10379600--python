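"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`CmcgameError`, so callers (and the CLI) can catch one type.
"""


class CmcgameError(Exception):
    """Base class for all cmcgame errors."""


class ConfigurationError(CmcgameError):
    """A required symbol is missing or an unknown key was supplied."""


class ParameterError(CmcgameError, ValueError):
    """A parameter value violates its admissible range."""


class DomainError(CmcgameError, ValueError):
    """A strategy probability lies outside the unit interval."""


class UsageError(CmcgameError):
    """An operation was called with an inconsistent combination of inputs."""


class NumericalError(CmcgameError):
    """A simulation produced a non-finite state.

    Attributes
    ----------
    step : int
        Index of the Euler step at which the failure was detected.
    """

    def __init__(self, message: str, step: int):
        super().__init__(message)
        self.step = step
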
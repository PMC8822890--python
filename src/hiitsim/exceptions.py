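"""Exception hierarchy shared by all hiitsim modules."""


class HiitSimError(Exception):
    """Base class for all hiitsim errors."""


class ProfileValidationError(HiitSimError, ValueError):
    """A power-duration profile violates its invariants or is incomplete."""


class DurationOutOfRangeError(HiitSimError, ValueError):
    """A duration falls outside the tabulated power-duration range."""


class InsufficientDataError(HiitSimError, ValueError):
    """Too few data points for the requested fit."""


class ModelDomainError(HiitSimError, ValueError):
    """An operation was invoked outside its physiological model domain."""


class SeriesTooShortError(HiitSimError, ValueError):
    """Power series shorter than the 30 s needed to compute Normalized Power."""


class NoSolutionError(HiitSimError, RuntimeError):
    """The intensity solver has no root inside its physical bracket."""
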
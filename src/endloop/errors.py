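"""Exception hierarchy for the endloop package."""


class EndloopError(Exception):
    """Base class for all package errors."""


class DomainError(EndloopError, ValueError):
    """An argument is outside the operation's domain (empty sample, negative width...)."""


class ParseError(EndloopError, ValueError):
    """A sequence or structure file could not be parsed; message names the offending entry."""


class EngineError(EndloopError, RuntimeError):
    """The external folding engine is missing or failed."""


class FitError(EndloopError, RuntimeError):
    """A model fit did not converge; carries the initial guesses and a data summary."""
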
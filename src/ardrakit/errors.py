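"""Exception hierarchy shared across the package."""


class ArdraError(Exception):
    """Base class for all ardrakit errors."""


class ParseError(ArdraError):
    """A file could not be parsed; the message names the offending location."""


class ValidationError(ArdraError):
    """An input value violates a documented precondition."""


class GenerationError(ArdraError):
    """A synthetic population spec is infeasible or generation did not converge."""
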
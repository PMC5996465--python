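"""Exception hierarchy shared across the pipeline stages."""


class CdrenetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CdrenetError, ValueError):
    """A configuration value violates its stated constraint."""


class ParseError(CdrenetError, ValueError):
    """An input file could not be parsed; message names the offending row/ID."""


class AlignmentError(CdrenetError, ValueError):
    """Two matrices share too few samples to be paired."""


class DomainError(CdrenetError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class StructuralError(CdrenetError, ValueError):
    """A network violates bipartiteness or another structural invariant."""


class PreconditionError(CdrenetError, ValueError):
    """An operation was called on inputs that skip a required earlier stage."""
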
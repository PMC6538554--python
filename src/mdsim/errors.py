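"""Exception hierarchy shared across the package."""


class MdsimError(Exception):
    """Base class for all package errors."""


class ParseError(MdsimError):
    """Raised for malformed OBO input; the message names the offending line."""


class StructuralError(MdsimError):
    """Raised when an ontology violates structural contracts (e.g. a cycle)."""


class LookupError_(MdsimError):
    """Raised when a term or resource id cannot be resolved."""


class ConfigurationError(MdsimError):
    """Raised for invalid run parameters (empty corpus, infeasible k, ...)."""


class InputError(MdsimError):
    """Raised when an input file yields no usable data."""
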
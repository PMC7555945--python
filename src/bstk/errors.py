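"""Exception types shared across the toolkit."""


class BstkError(Exception):
    """Base class for all toolkit errors."""


class ParseError(BstkError):
    """A file could not be parsed; the message names the offending line."""


class StructuralError(BstkError):
    """An input violates a structural invariant (e.g. a cyclic ontology)."""


class ValidationError(BstkError):
    """Inconsistent or out-of-range values in otherwise well-formed input."""
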
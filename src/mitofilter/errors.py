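"""Exception hierarchy."""


class MitofilterError(Exception):
    """Base class for all package errors."""


class ValidationError(MitofilterError):
    """A domain object violates its invariants, or inputs violate a contract."""


class ParseError(MitofilterError):
    """An input file could not be parsed; carries file/line context in the message."""
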
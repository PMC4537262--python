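"""Exception types shared across pankit."""


class PankitError(Exception):
    """Base class for all pankit errors."""


class ParameterError(PankitError, ValueError):
    """A parameter is outside its declared range."""


class ParseError(PankitError, ValueError):
    """An input file violates its format contract."""


class DomainError(PankitError, ValueError):
    """An operation was requested on data outside its domain."""
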
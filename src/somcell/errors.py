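"""Exception hierarchy shared across the pipeline."""


class SomcellError(Exception):
    """Base class for all package errors."""


class ValidationError(SomcellError):
    """Input data violates a structural invariant (duplicate ids, NaN, ...)."""


class ParseError(SomcellError):
    """A file could not be parsed; the message names the offending line."""


class ConfigurationError(SomcellError):
    """A parameter combination that cannot be acted on."""


class EmptyResultError(SomcellError):
    """An operation removed everything it was given."""
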
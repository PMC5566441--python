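"""Exception hierarchy shared across the pipeline."""


class SelfieError(Exception):
    """Base class for all package errors."""


class ValidationError(SelfieError, ValueError):
    """Input data violates a structural contract (missing wells, bad layout...)."""


class ParseError(SelfieError, ValueError):
    """A delimited-text input could not be parsed."""


class ContractError(SelfieError, ValueError):
    """An operation was called with arguments outside its domain."""


class SaturationError(SelfieError, ValueError):
    """Requested template load is beyond what partition statistics can resolve."""
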
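"""Exception hierarchy shared across the pipeline."""


class PespError(Exception):
    """Base class for all package errors."""


class ValidationError(PespError, ValueError):
    """Input data violates a documented precondition."""


class ConfigurationError(PespError, ValueError):
    """A configuration value is inconsistent or out of range."""
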
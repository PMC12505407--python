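"""Exception types shared across the pipeline."""


class DigiphenError(Exception):
    """Base class for all package errors."""


class ValidationError(DigiphenError, ValueError):
    """Malformed input data (out-of-range coordinates, non-alternating
    event streams, wrong item counts, ...)."""


class ConfigError(DigiphenError, ValueError):
    """Invalid generative or run configuration."""


class IntegrityError(DigiphenError, ValueError):
    """Cross-record inconsistency, e.g. a response referencing a prompt
    that was never sent."""


class InsufficientDataError(DigiphenError, ValueError):
    """Raised when an operation cannot produce a defined result; callers
    that aggregate daily features catch this and record a missing value
    (never an imputed one)."""
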
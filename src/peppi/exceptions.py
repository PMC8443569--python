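"""Exception hierarchy shared across the package."""


class PeppiError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PeppiError, ValueError):
    """Raised when user-supplied data violates a precondition."""


class ConfigurationError(PeppiError, ValueError):
    """Raised when a configuration object is internally inconsistent."""


class ProviderError(PeppiError, RuntimeError):
    """Raised when an external feature provider returns malformed output."""


class UndefinedMetricError(PeppiError, ValueError):
    """Raised when a metric is requested on degenerate input (e.g. one class)."""
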
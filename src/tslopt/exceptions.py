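"""Exception hierarchy shared across the package."""


class TsloptError(Exception):
    """Base class for all package errors."""


class DomainError(TsloptError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ConfigError(TsloptError, ValueError):
    """A configuration value is missing, unknown, or out of range."""


class FitError(TsloptError, RuntimeError):
    """Curve fitting cannot proceed (degenerate data, under-determined system)."""


class EvaluationError(TsloptError, RuntimeError):
    """A schedule cost could not be evaluated (e.g. every parameter sample degenerate)."""
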
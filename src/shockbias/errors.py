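"""Exception hierarchy shared across the package."""


class ShockbiasError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ShockbiasError):
    """A configuration value violates the schema or a type invariant."""


class DomainError(ShockbiasError):
    """A numeric input lies outside its mathematical or physiologic domain."""


class CorrelationError(ShockbiasError):
    """A correlation value or matrix is invalid (range, structure, or signs)."""


class StructuralError(ShockbiasError):
    """Inputs that must be aligned or well-formed (tables, matrices) are not."""
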
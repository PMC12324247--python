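"""Exception types shared across the package."""


class MemcultError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MemcultError, ValueError):
    """A parameter combination violates a design constraint (e.g. divisibility)."""


class ValidationError(MemcultError, ValueError):
    """Input data violates a documented contract (range, coverage, alignment)."""
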
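"""Exception types shared across the package."""


class MetabotyperError(Exception):
    """Base class for package errors."""


class ConfigError(MetabotyperError, ValueError):
    """Invalid configuration or generator parameters."""


class SchemaError(MetabotyperError, ValueError):
    """Input table violates the expected schema or invariants."""
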
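"""Exception hierarchy shared across the package."""


class OGDError(Exception):
    """Base class for all package errors."""


class ValidationError(OGDError, ValueError):
    """A value violates a documented precondition or invariant."""


class SchemaError(OGDError, ValueError):
    """An input file is structurally malformed (missing columns, bad keys)."""


class ConfigError(OGDError, ValueError):
    """A run configuration is invalid (missing paths, bad options)."""
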
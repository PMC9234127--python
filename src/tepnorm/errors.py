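"""Exception hierarchy shared across the package."""


class TepnormError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TepnormError):
    """A file could not be parsed (malformed cell, bad header, ...)."""


class ValidationError(TepnormError):
    """Input data violates an invariant (duplicates, negatives, coverage)."""


class ConfigError(TepnormError):
    """A configuration value is missing, unknown or inconsistent."""
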
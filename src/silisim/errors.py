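"""Exception hierarchy for silisim.

``ValidationError`` covers every bad-input condition (CLI maps it to exit
code 2); anything else raised at runtime maps to exit code 1.
"""


class SilisimError(Exception):
    """Base class for all package errors."""


class ValidationError(SilisimError, ValueError):
    """Invalid user input: bad value, bad unit, bad config."""


class ConfigError(ValidationError):
    """Configuration file violates the schema."""


class UnsupportedSpeciesError(ValidationError):
    """A silicate species outside the supported enumeration."""


class CoverageError(ValidationError):
    """Environment series does not cover the requested season."""
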
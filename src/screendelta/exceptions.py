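"""Typed errors and warnings shared across the package.

Validation is total: malformed inputs raise one of these, never a silent
coercion.
"""


class ScreenDeltaError(Exception):
    """Base class for all screendelta errors."""


class FormatError(ScreenDeltaError, ValueError):
    """A file or table violates its format contract (names the offending cell/line)."""


class ConfigurationError(ScreenDeltaError, ValueError):
    """Inputs are individually well-formed but inconsistent with each other or with the requested analysis."""


class AmbiguityError(ScreenDeltaError, ValueError):
    """An identifier mapping is ambiguous (one name, several targets)."""


class ScreenDeltaWarning(UserWarning):
    """Non-fatal data issues: dropped guides, deduplicated set items, unmapped ids."""
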
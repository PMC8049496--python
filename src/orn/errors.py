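"""Exception hierarchy shared across the package.

All errors subclass :class:`ValueError` so callers that do not care about
the fine distinction can catch a single type.
"""


class ORNError(ValueError):
    """Base class for all package errors."""


class ShapeError(ORNError):
    """Matrix dimensions are inconsistent with the requested operation."""


class DomainError(ORNError):
    """A numeric value lies outside its mathematically valid domain."""


class FormatError(ORNError):
    """An input table violates the expected format (type, NaN, raggedness)."""


class AlignmentError(ORNError):
    """Two tables share no common samples or cannot be aligned."""


class ConfigError(ORNError):
    """A configuration value is invalid or internally inconsistent."""
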
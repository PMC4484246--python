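"""Exception hierarchy shared across the package."""


class DegnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DegnetError):
    """A file does not conform to its documented tabular format."""


class ValidationError(DegnetError):
    """Parsed content violates a domain invariant."""


class DataError(DegnetError):
    """A value inside otherwise well-formed data is unusable."""
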
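"""Exception hierarchy shared across the pipeline stages."""


class MethretainError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MethretainError):
    """A file does not follow the expected dialect (missing column, bad header)."""


class ValidationError(MethretainError):
    """Parsed content violates a domain invariant (range, uniqueness, labels)."""


class SampleLookupError(MethretainError, KeyError):
    """A requested sample id is absent from a matrix or sample sheet."""


class EmptyDataError(MethretainError):
    """An operation received no usable (non-missing) data."""


class DegenerateInputError(MethretainError):
    """Counts or parameters make the requested statistic undefined."""


class ConfigError(MethretainError):
    """A configuration object or file is invalid (unknown key, bad value)."""
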
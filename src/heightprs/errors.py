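"""Exception hierarchy shared across the package."""


class HeightPRSError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HeightPRSError):
    """A parameter value is outside its documented domain."""


class FormatError(HeightPRSError):
    """An input file does not conform to its declared dialect."""


class IntegrityError(HeightPRSError):
    """Cross-table consistency violated (id mismatch, split overlap, ...)."""
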
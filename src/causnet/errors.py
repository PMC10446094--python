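"""Exception hierarchy shared across the package."""


class CausnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CausnetError):
    """A file does not have the expected structure (e.g. a missing column)."""


class ValidationError(CausnetError):
    """Data parsed fine but violates a domain invariant."""


class ConfigurationError(CausnetError):
    """An illegal model or generator configuration value."""


class DegenerateInputError(CausnetError):
    """An input that makes the requested operation meaningless (e.g. all-zero counts)."""


class NumericError(CausnetError):
    """A non-finite quantity appeared during training."""
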
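"""Exception hierarchy shared across the package."""


class SpeechDxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpeechDxError):
    """A file or table does not conform to the expected schema."""


class ValidationError(SpeechDxError):
    """An argument or configuration value violates a precondition."""


class ConfigurationError(SpeechDxError):
    """A configuration is incomplete or inconsistent (e.g. missing stats)."""


class InsufficientDataError(SpeechDxError):
    """Not enough data to compute the requested quantity."""


class DegenerateFeatureError(SpeechDxError):
    """A feature column is constant or otherwise unusable."""
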
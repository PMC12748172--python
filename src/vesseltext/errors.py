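"""Package-wide exception types."""


class VesseltextError(Exception):
    """Base class for package errors."""


class ValidationError(VesseltextError, ValueError):
    """Data violates an invariant (e.g. duplicate image ids)."""


class FormatError(VesseltextError, ValueError):
    """A file exists but is not in the expected format."""


class BackendUnavailableError(VesseltextError, RuntimeError):
    """A requested optional backend (e.g. a pretrained text encoder) is absent."""


class ConfigError(VesseltextError, ValueError):
    """Invalid model/training configuration."""
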
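"""Typed exceptions shared across the package."""


class PanelITSError(Exception):
    """Base class for all package errors."""


class ValidationError(PanelITSError):
    """Malformed or inconsistent input data."""


class FormatError(PanelITSError):
    """Unparseable file content (dates, headers, YAML)."""


class ConfigurationError(PanelITSError):
    """Invalid simulation or model configuration."""


class FitError(PanelITSError):
    """Model fitting failed in a way that cannot be reported as a result."""
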
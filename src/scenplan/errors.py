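"""Shared exception types."""


class ConfigurationError(ValueError):
    """Invalid generator or model configuration."""


class AlignmentError(ValueError):
    """Rasters that must share a shape do not."""
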
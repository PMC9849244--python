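"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """A module was configured inconsistently (channels, dilation, flags)."""


class ShapeError(ValueError):
    """An input does not satisfy a shape precondition."""


class ValidationError(ValueError):
    """Data failed validation (non-binary mask, mismatched resolution, ...)."""
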
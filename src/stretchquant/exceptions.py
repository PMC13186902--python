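"""Error and warning types shared across the pipeline."""


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


class DegenerateImageError(ValidationError):
    """Raised when an image has too little dynamic range to threshold."""


class IllConditionedError(ValidationError):
    """Raised when a geometric fit has no unique solution (e.g. collinear points)."""


class DegenerateDataWarning(UserWarning):
    """Emitted when a stage produces an empty or degenerate (but valid) result."""
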
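"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(ValidationError):
    """A file does not conform to the expected on-disk format."""


class ShapeError(ValidationError):
    """Array shapes are inconsistent with the model or data contract."""
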
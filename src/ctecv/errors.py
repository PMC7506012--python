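"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class SegmentationError(RuntimeError):
    """LV delineation failed (empty cavity, degenerate geometry, ...)."""


class RegistrationError(RuntimeError):
    """Registration could not be run on the given pair of volumes."""
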
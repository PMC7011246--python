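"""Exception hierarchy shared across the pipeline stages."""


class RadiotexError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RadiotexError):
    """An invalid parameter or configuration field; the message names the field."""


class DegenerateInputError(RadiotexError):
    """Input too small or too uniform for the requested computation."""


class EmptyMaskError(DegenerateInputError):
    """A tumor mask with no foreground pixels."""


class ShapeMismatchError(RadiotexError):
    """Image and mask arrays do not share a shape."""


class UndefinedCorrelationError(DegenerateInputError):
    """Pearson correlation requested for a zero-variance vector."""


class PipelineStageError(RadiotexError):
    """A pipeline stage failed; carries the stage name and, when known, the subject."""

    def __init__(self, stage: str, message: str, subject_id: str | None = None):
        self.stage = stage
        self.subject_id = subject_id
        where = f"stage '{stage}'" + (f", subject '{subject_id}'" if subject_id else "")
        super().__init__(f"{where}: {message}")
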
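"""Exception hierarchy shared across the pipeline."""


class InvpapError(Exception):
    """Base class for all package errors."""


class ParseError(InvpapError):
    """An input file could not be parsed; message names the offending line."""


class ValidationError(InvpapError):
    """An input violates a documented precondition or invariant."""


class StageError(InvpapError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
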
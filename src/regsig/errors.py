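"""Exception hierarchy shared across the package."""


class RegsigError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RegsigError, ValueError):
    """A tuning parameter is outside its documented range."""


class InvalidInputError(RegsigError, ValueError):
    """Input data violates a documented contract."""


class PipelineError(RegsigError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
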
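"""Exception hierarchy shared across the package."""


class PetgateError(Exception):
    """Base class for all petgate errors."""


class ParameterError(PetgateError, ValueError):
    """A supplied parameter violates a documented precondition."""


class StageError(PetgateError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
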
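"""Exception hierarchy for the firstspike pipeline."""


class FirstspikeError(Exception):
    """Base class for all package errors."""


class SchemaError(FirstspikeError):
    """A file is missing a required column or field."""


class ValidationError(FirstspikeError):
    """Data violate a documented invariant (e.g. negative hold time)."""


class StageError(FirstspikeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause!r}")
        self.stage = stage
        self.cause = cause
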
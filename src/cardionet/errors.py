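"""Exception types raised across the pipeline."""


class CardionetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CardionetError):
    """An invalid configuration value; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class ParseError(CardionetError):
    """A malformed input file; the message names file and line."""

    def __init__(self, path, line: int | None, message: str):
        self.path = str(path)
        self.line = line
        loc = f"{path}" if line is None else f"{path}:{line}"
        super().__init__(f"{loc}: {message}")


class DegenerateInputError(CardionetError):
    """Input whose statistics are undefined (zero variance, empty class, ...)."""


class PipelineError(CardionetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
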
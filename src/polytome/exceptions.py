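"""Exception hierarchy shared by all polytome modules."""


class PolytomeError(Exception):
    """Base class for all errors raised by polytome."""


class ConfigurationError(PolytomeError):
    """A configuration value, column mapping, or argument is invalid."""


class ParseError(PolytomeError):
    """An input file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ContractError(PolytomeError):
    """An internal precondition was violated (e.g. stages run out of order)."""


class PipelineError(PolytomeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
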
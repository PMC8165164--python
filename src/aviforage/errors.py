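"""Exception hierarchy for the arena-foraging pose pipeline."""


class AviforageError(Exception):
    """Base class for all package errors."""


class ConfigError(AviforageError):
    """Invalid simulation or run configuration."""


class FormatError(AviforageError):
    """Malformed trajectory/manifest file; carries the offending line when known."""

    def __init__(self, message, path=None, line=None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)


class SchemaError(AviforageError):
    """A required bodypart or column is missing."""


class EmptyTrajectoryError(AviforageError):
    """No usable frames remain after trimming or filtering."""


class ParameterError(AviforageError):
    """A numerical parameter is outside its valid range."""


class DomainError(AviforageError):
    """An input value lies outside the mathematical domain of an operation."""


class InputError(AviforageError):
    """Input data violates a precondition (e.g. empty bins, mismatched series)."""


class PipelineError(AviforageError):
    """A pipeline stage failed; names the stage and the offending input."""

    def __init__(self, stage, message, path=None):
        self.stage = stage
        self.path = path
        suffix = f" (input: {path})" if path is not None else ""
        super().__init__(f"stage '{stage}': {message}{suffix}")
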
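"""Exception hierarchy shared across the package."""


class MotisynError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MotisynError, ValueError):
    """Input file violates the expected record structure."""


class SchemaError(FormatError):
    """Tabular input is missing required columns."""


class ParseError(FormatError):
    """Input file could not be parsed at all."""


class DegenerateInputError(MotisynError, ValueError):
    """Input is structurally valid but too small/degenerate for the operation."""


class ConfigError(MotisynError, ValueError):
    """Invalid configuration or parameter value."""


class PipelineError(MotisynError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
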
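"""Exception types shared across the package."""


class RumenauxError(Exception):
    """Base class for all package errors."""


class SchemaError(RumenauxError, ValueError):
    """A tabular input is missing required columns or violates its schema."""


class TableParseError(RumenauxError, ValueError):
    """A value inside a tabular input could not be parsed."""


class DefinitionParseError(RumenauxError, ValueError):
    """A KEGG module DEFINITION string is malformed.

    Carries the character offset at which parsing failed.
    """

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)
        self.offset = offset


class ConsistencyError(RumenauxError, ValueError):
    """Cross-table references do not line up (e.g. unknown genome id)."""


class StageError(RumenauxError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
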
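"""Exception hierarchy used across the package."""


class TcrTrackError(Exception):
    """Base class for all package errors."""


class DialectError(TcrTrackError):
    """Clonotype file dialect unknown or ambiguous."""


class SchemaError(TcrTrackError):
    """A mandatory column is missing from an input table."""


class RowParseError(TcrTrackError):
    """A single row could not be parsed; carries the 0-based row index."""

    def __init__(self, row_index: int, message: str):
        super().__init__(f"row {row_index}: {message}")
        self.row_index = row_index


class IntegrityError(TcrTrackError):
    """Cross-record consistency violated (duplicate IDs, unknown samples...)."""


class ParameterError(TcrTrackError):
    """A parameter value outside its documented range."""


class EmptyRepertoireError(TcrTrackError):
    """An operation that needs a non-empty repertoire got an empty one."""


class ConfigError(TcrTrackError):
    """Invalid simulation or pipeline configuration."""


class SignatureError(TcrTrackError):
    """No signature gene present in the expression matrix."""


class ValidationError(TcrTrackError):
    """A measurement outside its physically valid range."""
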
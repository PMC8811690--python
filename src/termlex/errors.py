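"""Exception hierarchy for termlex."""


class TermlexError(Exception):
    """Base class for all termlex errors."""


class ExportParseError(TermlexError):
    """Raised when a concept export is not valid JSON (or JSON-lines)."""


class ExportValidationError(TermlexError):
    """Raised when a parsed concept record is missing a required field."""


class MetadataSchemaError(TermlexError):
    """Raised when a metadata table lacks a required column."""


class MetadataValidationError(TermlexError):
    """Raised when a metadata value is outside its enumeration."""


class UndefinedDensityError(TermlexError):
    """Raised when lexical density is requested for zero total words."""
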
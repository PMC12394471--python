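"""Exception hierarchy.

Every error raised on purpose by goforge derives from :class:`GoforgeError`
so the CLI can map categories to exit messages without string matching.
"""


class GoforgeError(Exception):
    """Base class for all goforge errors."""


class InputError(GoforgeError):
    """Semantically invalid input (bad sizes, study not in universe, ...)."""


class FormatError(GoforgeError):
    """A table or file does not follow the expected dialect."""


class OboParseError(GoforgeError):
    """Malformed OBO stanza; carries the stanza ordinal."""

    def __init__(self, message: str, stanza_ordinal: int | None = None):
        if stanza_ordinal is not None:
            message = f"stanza #{stanza_ordinal}: {message}"
        super().__init__(message)
        self.stanza_ordinal = stanza_ordinal


class TabularParseError(GoforgeError):
    """Malformed row in a tab-delimited stream; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(GoforgeError):
    """A structural invariant (e.g. acyclicity) is violated."""


class OntologyLookupError(GoforgeError, KeyError):
    """Unknown GO accession; carries the offending id."""

    def __init__(self, go_id: str):
        super().__init__(f"unknown GO accession: {go_id}")
        self.go_id = go_id

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]


class ConfigurationError(GoforgeError):
    """Runtime configuration problem (e.g. no aligner and no precomputed hits)."""
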
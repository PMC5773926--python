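"""Exception hierarchy.

Usage errors (bad arguments) raise :class:`UsageError`; malformed or
inconsistent data raises :class:`DataError` subclasses.  The CLI maps the
former to exit code 1 and the latter to exit code 2.
"""


class FragpickError(Exception):
    """Base class for all fragpick errors."""


class UsageError(FragpickError):
    """Invalid arguments or option combinations."""


class DataError(FragpickError):
    """Malformed or inconsistent input data."""


class IncompatibleFragmentsError(DataError):
    """Point sets / fragments with mismatched atom counts."""


class UnderdeterminedSuperpositionError(DataError):
    """Fewer than 3 points: rigid superposition is underdetermined."""


class PdbParseError(DataError):
    """A PDB file or record could not be parsed."""


class BinaryFormatError(DataError):
    """Base for binary database/index stream problems."""


class BadMagicError(BinaryFormatError):
    """Stream does not start with the expected magic bytes."""


class VersionMismatchError(BinaryFormatError):
    """Stream format version is not supported."""


class TruncatedStreamError(BinaryFormatError):
    """Stream ended prematurely.

    ``ordinal`` is the index of the fragment (or table) being read when
    the stream ran out, or ``None`` if it died inside the header.
    """

    def __init__(self, message: str, ordinal: int | None = None):
        super().__init__(message)
        self.ordinal = ordinal


class IndexMismatchError(DataError):
    """Index was built for a different database (content hash differs)."""


class InvalidRegexError(UsageError):
    """Sequence constraint is not a valid regular expression."""

    def __init__(self, pattern: str, reason: str):
        super().__init__(f"invalid sequence regex {pattern!r}: {reason}")
        self.pattern = pattern
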
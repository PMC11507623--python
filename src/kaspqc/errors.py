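"""Exception hierarchy for input validation.

Every error raised while reading a genotype table derives from
:class:`InputError`, so callers (the CLI in particular) can map failure
modes to distinct exit codes without string matching.
"""

from __future__ import annotations


class InputError(Exception):
    """Base class for all genotype-table input problems."""


class HeaderError(InputError):
    """A mandatory header column is missing or no marker columns exist."""


class CallParseError(InputError):
    """A genotype cell could not be parsed as a diploid call.

    Carries the offending text plus 1-based row number and column label
    when raised from table reading.
    """

    def __init__(self, raw: str, reason: str, row: int | None = None,
                 column: str | None = None):
        self.raw = raw
        self.reason = reason
        self.row = row
        self.column = column
        loc = ""
        if row is not None or column is not None:
            loc = f" (row {row}, column {column!r})"
        super().__init__(f"cannot parse genotype call {raw!r}{loc}: {reason}")


class RoleError(InputError):
    """The 'Type' column holds a token that is neither a parent nor an F1."""

    def __init__(self, token: str, row: int):
        self.token = token
        self.row = row
        super().__init__(
            f"unrecognized sample type {token!r} at row {row}; "
            "expected a parent or F1 designation"
        )


class DuplicateSampleError(InputError):
    """Two rows share the same Sample ID."""

    def __init__(self, duplicates: list[str]):
        self.duplicates = duplicates
        super().__init__(f"duplicate Sample ID values: {', '.join(duplicates)}")


class FamilyStructureError(InputError):
    """Rows cannot be partitioned into (2 parents + offspring) blocks."""


class EmptyTableError(InputError):
    """The file has a header but no data rows."""
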
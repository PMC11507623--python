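"""Read, validate and normalize Intertek-dialect KASP genotype tables.

The Intertek KASP export is a flat grid: three leading identifier columns
("Sample ID", "Sample Name", "Type") followed by one column per SNP
marker.  Cells hold diploid nucleotide calls ("A:G", "T:T", ...) or a
missing-data code ("?" / "Uncallable").  Rows are organized positionally:
each bi-parental cross appears as its two parent rows immediately followed
by the putative F1 offspring of that cross, and several crosses may be
stacked in one file.

This module parses that dialect into plain dataclasses, groups rows into
cross families, and can write a normalized copy back out (XLSX, CSV or
TSV).  All downstream QC works on the structures defined here.
"""

from __future__ import annotations

import enum
import functools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

from .errors import (
    CallParseError,
    DuplicateSampleError,
    EmptyTableError,
    FamilyStructureError,
    HeaderError,
    RoleError,
)

__all__ = [
    "GenotypeCall",
    "MISSING_CALL",
    "Role",
    "SampleRecord",
    "CrossFamily",
    "GenotypeTable",
    "Dialect",
    "normalize_call",
    "group_families",
    "read_table",
    "write_table",
]

VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class GenotypeCall:
    """One diploid genotype call: an unordered allele pair, or missing.

    ``alleles`` is either ``None`` (missing call) or a 2-tuple of
    nucleotide symbols stored in alphabetical order so that the call built
    from (G, A) compares equal to the one built from (A, G).
    """

    alleles: tuple[str, str] | None

    def __post_init__(self) -> None:
        if self.alleles is not None:
            a, b = self.alleles
            if a not in VALID_ALLELES or b not in VALID_ALLELES:
                raise ValueError(f"invalid alleles {self.alleles!r}")
            if (a, b) != tuple(sorted((a, b))):
                object.__setattr__(self, "alleles", tuple(sorted((a, b))))

    @property
    def missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        """True for a heterozygous (two distinct alleles) call."""
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def is_hom(self) -> bool:
        return self.alleles is not None and self.alleles[0] == self.alleles[1]

    @property
    def allele_set(self) -> frozenset[str]:
        return frozenset(self.alleles) if self.alleles else frozenset()

    def __str__(self) -> str:
        if self.alleles is None:
            return "?"
        return f"{self.alleles[0]}:{self.alleles[1]}"


MISSING_CALL = GenotypeCall(None)


class Role(enum.Enum):
    PARENT = "PARENT"
    F1 = "F1"


@dataclass
class SampleRecord:
    """One input row: identifiers, role, and calls across all markers."""

    sample_id: str
    sample_name: str
    role: Role
    calls: dict[str, GenotypeCall]  # marker_id -> call, in column order


@dataclass
class CrossFamily:
    """Two parents and their putative F1 offspring — the QC unit."""

    parent1: SampleRecord
    parent2: SampleRecord
    offspring: list[SampleRecord] = field(default_factory=list)
    family_index: int = 1

    def __post_init__(self) -> None:
        if self.parent1.role is not Role.PARENT or self.parent2.role is not Role.PARENT:
            raise ValueError("family parents must have role PARENT")
        if any(o.role is not Role.F1 for o in self.offspring):
            raise ValueError("family offspring must have role F1")

    @property
    def samples(self) -> list[SampleRecord]:
        return [self.parent1, self.parent2, *self.offspring]


@dataclass
class GenotypeTable:
    """A whole input file: marker column order plus the cross families."""

    marker_ids: list[str]
    families: list[CrossFamily]

    def __post_init__(self) -> None:
        if not self.marker_ids:
            raise ValueError("marker_ids must be non-empty")

    @property
    def samples(self) -> list[SampleRecord]:
        return [s for fam in self.families for s in fam.samples]

    @property
    def n_offspring(self) -> int:
        return sum(len(f.offspring) for f in self.families)

    def iter_rows(self) -> Iterator[tuple[CrossFamily, SampleRecord]]:
        for fam in self.families:
            for rec in fam.samples:
                yield fam, rec


# ---------------------------------------------------------------------------
# Dialect configuration


@dataclass(frozen=True)
class Dialect:
    """Parser configuration for the Intertek grid and near-variants."""

    id_column: str = "Sample ID"
    name_column: str = "Sample Name"
    type_column: str = "Type"
    missing_codes: frozenset[str] = frozenset({"?", "uncallable", ""})
    parent_tokens: frozenset[str] = frozenset({"parent", "p"})
    f1_tokens: frozenset[str] = frozenset({"f1", "f_1", "offspring"})
    sheet: str | int = 0

    def parse_role(self, token: str, row: int) -> Role:
        t = token.strip().lower()
        if t in self.parent_tokens:
            return Role.PARENT
        if t in self.f1_tokens:
            return Role.F1
        raise RoleError(token, row)


DEFAULT_DIALECT = Dialect()

_CALL_RE = re.compile(r"^([A-Z])[:/]?([A-Z])$")


def normalize_call(raw_cell: str,
                   missing_codes: frozenset[str] = DEFAULT_DIALECT.missing_codes,
                   ) -> GenotypeCall:
    """Parse one raw genotype cell into a canonical :class:`GenotypeCall`.

    Accepts "X:Y", "X/Y", "XY" and the single-letter homozygote shorthand
    "X", case-insensitively; "?" / "Uncallable" / blank cells become the
    missing call.  The allele pair is canonicalized to alphabetical order.

    Raises :class:`CallParseError` for anything else (more than two
    alleles, non-nucleotide letters, stray characters).
    """
    text = raw_cell.strip()
    if text.lower() in missing_codes:
        return MISSING_CALL
    return _parse_call_cached(text.upper())


@functools.lru_cache(maxsize=65536)
def _parse_call_cached(up: str) -> GenotypeCall:
    if len(up) == 1:
        if up in VALID_ALLELES:
            return GenotypeCall((up, up))
        raise CallParseError(up, "not a nucleotide (A, C, G, T)")
    m = _CALL_RE.match(up)
    if m is None:
        if re.fullmatch(r"[A-Z](?:[:/][A-Z]){2,}", up) or re.fullmatch(r"[A-Z]{3,}", up):
            raise CallParseError(up, "more than two alleles (diploid calls only)")
        raise CallParseError(up, "expected two nucleotides like 'A:G', 'A/G' or 'AG'")
    a, b = m.group(1), m.group(2)
    bad = [x for x in (a, b) if x not in VALID_ALLELES]
    if bad:
        raise CallParseError(up, f"invalid allele(s) {', '.join(bad)}")
    return GenotypeCall((a, b))


def group_families(rows: Sequence[SampleRecord]) -> list[CrossFamily]:
    """Partition file-ordered rows into bi-parental cross families.

    The grouping is purely positional: every maximal run of consecutive
    PARENT rows must have length exactly two and opens a new family; the
    F1 rows that follow (until the next PARENT row) are its offspring.
    """
    families: list[CrossFamily] = []
    i, n = 0, len(rows)
    if n and rows[0].role is Role.F1:
        raise FamilyStructureError(
            f"file starts with an F1 row ({rows[0].sample_id!r}) "
            "before any parent pair"
        )
    while i < n:
        j = i
        while j < n and rows[j].role is Role.PARENT:
            j += 1
        run = j - i
        if run != 2:
            raise FamilyStructureError(
                f"rows {i + 1}-{j} contain a run of {run} consecutive parent "
                "rows; each cross must have exactly 2 parents"
            )
        k = j
        while k < n and rows[k].role is Role.F1:
            k += 1
        families.append(
            CrossFamily(
                parent1=rows[i],
                parent2=rows[i + 1],
                offspring=list(rows[j:k]),
                family_index=len(families) + 1,
            )
        )
        i = k
    return families


# ---------------------------------------------------------------------------
# File reading / writing


def _load_frame(path: Path, dialect: Dialect, fmt: str | None) -> pd.DataFrame:
    fmt = fmt or _infer_format(path)
    if fmt == "xlsx":
        return pd.read_excel(path, sheet_name=dialect.sheet, dtype=str,
                             keep_default_na=False, engine="openpyxl")
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"xlsx", "csv", "tsv"}:
        return suffix
    if suffix in {"txt", "tab"}:
        return "tsv"
    raise HeaderError(f"cannot infer table format from extension {path.suffix!r}")


def read_table(path: str | Path,
               dialect: Dialect = DEFAULT_DIALECT,
               fmt: str | None = None) -> GenotypeTable:
    """Read an Intertek-dialect genotype file into a :class:`GenotypeTable`.

    ``fmt`` may force "xlsx", "csv" or "tsv"; by default it is inferred
    from the file extension.  Raises subclasses of
    :class:`~kaspqc.errors.InputError` for malformed input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = _load_frame(path, dialect, fmt)
    frame.columns = [str(c).strip() for c in frame.columns]

    mandatory = (dialect.id_column, dialect.name_column, dialect.type_column)
    for col in mandatory:
        if col not in frame.columns:
            raise HeaderError(f"mandatory column {col!r} missing from header")
    marker_ids = [c for c in frame.columns if c not in mandatory]
    if not marker_ids:
        raise HeaderError("no SNP marker columns after the identifier columns")
    if frame.empty:
        raise EmptyTableError("file contains a header row but no sample rows")

    rows: list[SampleRecord] = []
    for pos, (_, r) in enumerate(frame.iterrows()):
        row_no = pos + 2  # 1-based, counting the header row
        role = dialect.parse_role(str(r[dialect.type_column]), row_no)
        calls: dict[str, GenotypeCall] = {}
        for marker in marker_ids:
            try:
                calls[marker] = normalize_call(str(r[marker]), dialect.missing_codes)
            except CallParseError as exc:
                raise CallParseError(exc.raw, exc.reason, row=row_no,
                                     column=marker) from None
        rows.append(
            SampleRecord(
                sample_id=str(r[dialect.id_column]).strip(),
                sample_name=str(r[dialect.name_column]).strip(),
                role=role,
                calls=calls,
            )
        )

    seen: dict[str, int] = {}
    for rec in rows:
        seen[rec.sample_id] = seen.get(rec.sample_id, 0) + 1
    dupes = sorted(sid for sid, cnt in seen.items() if cnt > 1)
    if dupes:
        raise DuplicateSampleError(dupes)

    return GenotypeTable(marker_ids=marker_ids, families=group_families(rows))


def _table_frame(table: GenotypeTable, dialect: Dialect) -> pd.DataFrame:
    records = []
    for fam, rec in table.iter_rows():
        row: dict[str, str] = {
            dialect.id_column: rec.sample_id,
            dialect.name_column: rec.sample_name,
            dialect.type_column: "Parent" if rec.role is Role.PARENT else "F1",
        }
        for marker in table.marker_ids:
            row[marker] = str(rec.calls[marker])
        records.append(row)
    cols = [dialect.id_column, dialect.name_column, dialect.type_column,
            *table.marker_ids]
    return pd.DataFrame.from_records(records, columns=cols)


def write_table(table: GenotypeTable, path: str | Path,
                dialect: Dialect = DEFAULT_DIALECT,
                fmt: str | None = None) -> Path:
    """Write a normalized copy of ``table`` (canonical "X:Y" calls, "?" for
    missing) in the same grid layout it was read from."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    frame = _table_frame(table, dialect)
    if fmt == "xlsx":
        frame.to_excel(path, index=False, engine="openpyxl")
    else:
        frame.to_csv(path, sep={"csv": ",", "tsv": "\t"}[fmt], index=False)
    return path
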
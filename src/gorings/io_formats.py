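"""Reading REVIGO exports and the intermediate three-column processing file.

REVIGO summarises a flat list of enriched GO terms into a two-level
hierarchy: every row carries a term ``description``, the ``representative``
(parent) term of its semantic cluster, and a log10 enrichment p-value.  A
term whose representative field is ``null`` (or empty) is its own
representative, i.e. a parent.  This module ingests such exports into
:class:`GOTermRecord` lists and round-trips the sorted records through a
small tab-delimited processing file that downstream steps consume.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence, Union

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Delimiters considered by the sniffer, in tie-break priority order.
CANDIDATE_DELIMITERS = (",", ";", "\t")

#: Header of the intermediate processing file (tab-delimited, UTF-8).
INTERMEDIATE_HEADER = ("description", "representative", "value")

#: Case-insensitive substrings used to locate the required input columns.
_COLUMN_KEYS = {
    "description": "description",
    "representative": "representative",
    "value": "log10",
}

PathOrStream = Union[str, Path, IO[str]]


@dataclass(frozen=True)
class GOTermRecord:
    """One GO term: its label, its cluster representative, and its weight.

    ``value`` is the absolute log10 enrichment p-value; larger means more
    significant.  A parent term has ``representative == description``.
    """

    description: str
    representative: str
    value: float

    def __post_init__(self) -> None:
        if not self.description.strip():
            raise ValidationError("record description must be non-empty")
        if self.value < 0:
            raise ValidationError(
                f"record value must be non-negative, got {self.value!r}"
            )

    @property
    def is_parent(self) -> bool:
        return self.description == self.representative


@dataclass(frozen=True)
class IntermediateTable:
    """Sorted, de-duplicated records plus provenance of how they were read."""

    rows: tuple[GOTermRecord, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def validate(self) -> None:
        _check_no_duplicates(self.rows)
        _check_sorted(self.rows)


def sniff_delimiter(header_line: str) -> str:
    """Pick the delimiter occurring most often in the header line.

    Ties (including the no-delimiter case) resolve to comma, which is the
    most common REVIGO export dialect.
    """
    counts = {d: header_line.count(d) for d in CANDIDATE_DELIMITERS}
    best = max(counts.values())
    for d in CANDIDATE_DELIMITERS:  # priority order breaks ties
        if counts[d] == best:
            return d
    return ","  # unreachable


def _read_text(source: PathOrStream) -> tuple[str, str]:
    if hasattr(source, "read"):
        text = source.read()
        name = getattr(source, "name", "<stream>")
    else:
        text = Path(source).read_text(encoding="utf-8-sig")
        name = str(source)
    # Tolerate a BOM on streams too.
    return text.lstrip("﻿"), name


def _locate_columns(header: Sequence[str]) -> dict[str, int]:
    lowered = [h.strip().lower() for h in header]
    indices: dict[str, int] = {}
    for role, key in _COLUMN_KEYS.items():
        for i, cell in enumerate(lowered):
            if key in cell:
                indices[role] = i
                break
        else:
            raise ParseError(
                f"missing required column matching {key!r} "
                f"(header: {', '.join(header) or '<empty>'})"
            )
    return indices


def _check_no_duplicates(records: Sequence[GOTermRecord]) -> None:
    seen: set[tuple[str, str]] = set()
    for r in records:
        pair = (r.description, r.representative)
        if pair in seen:
            raise ValidationError(
                f"duplicate (description, representative) pair: {pair!r}"
            )
        seen.add(pair)


def _check_sorted(records: Sequence[GOTermRecord]) -> None:
    for a, b in zip(records, records[1:]):
        if b.value > a.value:
            raise ValidationError(
                "records are not sorted by non-increasing value "
                f"({a.value!r} precedes {b.value!r})"
            )


def parse_revigo(
    source: PathOrStream, delimiter: str | None = None
) -> list[GOTermRecord]:
    """Parse a REVIGO-style delimited table into term records.

    The three required columns are matched case-insensitively on the
    substrings ``description``, ``representative`` and ``log10`` anywhere in
    the header, so full REVIGO exports (with term_ID, frequency, uniqueness,
    dispensability, ...) parse unchanged.  The delimiter is sniffed from the
    header among comma/semicolon/tab unless given explicitly.

    Row handling follows the processing-file contract:

    * log10 p-values are absolute-valued (REVIGO prints them negative);
    * a ``null``/empty representative is replaced by the row's own
      description (the term is its own parent);
    * blank or NaN value cells drop the row with a warning;
    * zero values drop the row with a warning (a zero-weight slice is
      invisible and breaks gradient construction);
    * any other unparseable value raises :class:`ParseError` with the row
      number.
    """
    text, name = _read_text(source)
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise ParseError(f"{name}: empty input, no header row")

    delim = delimiter or sniff_delimiter(lines[0])
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    try:
        header = next(reader)
    except StopIteration:  # pragma: no cover - guarded above
        raise ParseError(f"{name}: empty input, no header row") from None
    cols = _locate_columns(header)

    records: list[GOTermRecord] = []
    n_data_rows = 0
    for lineno, row in enumerate(reader, start=2):
        if not row or not any(cell.strip() for cell in row):
            continue
        n_data_rows += 1
        cells = row + [""] * (max(cols.values()) + 1 - len(row))
        description = cells[cols["description"]].strip()
        if not description:
            raise ParseError(f"{name}: row {lineno}: empty description")
        raw_value = cells[cols["value"]].strip()
        if raw_value == "" or raw_value.lower() == "nan":
            logger.warning(
                "%s: row %d (%s): blank/NaN value, row skipped",
                name, lineno, description,
            )
            continue
        try:
            value = abs(float(raw_value))
        except ValueError:
            raise ParseError(
                f"{name}: row {lineno}: cannot parse value {raw_value!r}"
            ) from None
        if value != value:  # NaN that float() accepted, e.g. "NAN "
            logger.warning(
                "%s: row %d (%s): NaN value, row skipped",
                name, lineno, description,
            )
            continue
        if value == 0.0:
            logger.warning(
                "%s: row %d (%s): zero value, row dropped "
                "(invisible slice)", name, lineno, description,
            )
            continue
        representative = cells[cols["representative"]].strip()
        if not representative or representative.lower() == "null":
            representative = description
        records.append(GOTermRecord(description, representative, value))

    if n_data_rows == 0:
        raise ParseError(f"{name}: no data rows")
    _check_no_duplicates(records)
    return records


def write_intermediate(
    records: Sequence[GOTermRecord], path: str | Path
) -> None:
    """Write sorted records as the three-column tab-delimited processing file.

    Values are printed with 6 decimal places; labels containing tabs,
    quotes or newlines are quoted so the file round-trips losslessly
    through :func:`parse_intermediate`.
    """
    if not records:
        raise ValidationError("cannot write an empty record list")
    _check_sorted(records)
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(
            fh, delimiter="\t", lineterminator="\n", quoting=csv.QUOTE_MINIMAL
        )
        writer.writerow(INTERMEDIATE_HEADER)
        for r in records:
            writer.writerow([r.description, r.representative, f"{r.value:.6f}"])


def parse_intermediate(path: str | Path) -> IntermediateTable:
    """Read a processing file back into a validated :class:`IntermediateTable`.

    The table invariants (no duplicate (description, representative) pair,
    rows in non-increasing value order) are enforced; hand-authored files
    violating them raise :class:`ValidationError`.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8-sig", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if tuple(h.strip().lower() for h in header) != INTERMEDIATE_HEADER:
            raise ParseError(
                f"{path}: expected header {INTERMEDIATE_HEADER}, "
                f"got {tuple(header)}"
            )
        rows: list[GOTermRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) < 3:
                raise ParseError(f"{path}: row {lineno}: expected 3 columns")
            description = row[0].strip()
            representative = row[1].strip()
            if not representative or representative.lower() == "null":
                representative = description
            try:
                value = abs(float(row[2]))
            except ValueError:
                raise ParseError(
                    f"{path}: row {lineno}: cannot parse value {row[2]!r}"
                ) from None
            rows.append(GOTermRecord(description, representative, value))
    if not rows:
        raise ParseError(f"{path}: no data rows")
    table = IntermediateTable(
        rows=tuple(rows),
        provenance={"source": str(path), "delimiter": "\t"},
    )
    table.validate()
    return table
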
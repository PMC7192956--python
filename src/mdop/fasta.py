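"""FASTA parsing, writing, and the five sequence transforms.

The transforms prepare multiple-sequence FASTA files for database
submission: strip alignment gaps (``-``) so unaligned sequences are
uploaded, sort records shortest-to-longest for length screening, and
collapse duplicate records keyed either on the header (redundant entries)
or on the sequence itself (one representative per haplotype).

A document remembers whether its source was single-line (each sequence on
one line) or multi-line (wrapped, classically at 80 columns); the
command-line layer insists on single-line input for the four in-place
transforms and points users at the converter, while the library functions
here operate on parsed documents regardless of dialect.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import naming
from .errors import (
    AlreadyExistsError,
    EmptyAfterDegapError,
    InputPathError,
    MalformedRecordError,
    NotFastaError,
    OutputPathError,
)

__all__ = [
    "SINGLE_LINE",
    "MULTI_LINE",
    "FastaRecord",
    "FastaDocument",
    "read_fasta",
    "write_fasta_single_line",
    "degap",
    "rank_seq",
    "head_derep",
    "seq_derep",
    "multi_to_single_fasta",
]

logger = logging.getLogger(__name__)

SINGLE_LINE = "single_line"
MULTI_LINE = "multi_line"

GAP = "-"


@dataclass(frozen=True)
class FastaRecord:
    """One header (text after ``>``, verbatim) and one nucleotide sequence.

    Case is preserved; the sequence may contain ``-`` gap characters.
    Trailing whitespace on the header is trimmed (it is invisible in a file
    and would make header comparison ill-defined); everything else is kept
    as written.
    """

    header: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "header", self.header.rstrip())
        if not self.header:
            raise MalformedRecordError("record header is empty")
        if any(c.isspace() for c in self.sequence) or ">" in self.sequence:
            raise MalformedRecordError(
                f"sequence of {self.header!r} contains whitespace or '>'"
            )


@dataclass(frozen=True)
class FastaDocument:
    """An ordered collection of records plus the dialect they came from."""

    records: tuple[FastaRecord, ...] = field(default_factory=tuple)
    source_dialect: str = SINGLE_LINE

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def read_fasta(path: Path | str) -> FastaDocument:
    """Parse a FASTA file into a document, detecting its dialect.

    Multi-line sequences are concatenated. A UTF-8 BOM and leading blank
    lines are tolerated; blank lines between records are skipped with a
    warning. The dialect is ``single_line`` exactly when every record's
    sequence occupied one source line.

    Raises
    ------
    NotFastaError
        If no ``>`` definition line is found.
    MalformedRecordError
        For an empty header, an empty sequence, or ``>`` mid-line.
    """
    path = Path(path)
    if not path.is_file():
        raise InputPathError(f"not a readable file: {path}")
    text = path.read_text(encoding="utf-8-sig")

    records: list[FastaRecord] = []
    header: str | None = None
    chunks: list[str] = []
    max_chunks = 0
    saw_blank_interior = False

    def flush():
        nonlocal max_chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise MalformedRecordError(f"record {header!r} has an empty sequence")
        max_chunks = max(max_chunks, len(chunks))
        records.append(FastaRecord(header, seq))

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            if header is not None:
                saw_blank_interior = True
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].rstrip()
            if not header:
                raise MalformedRecordError("definition line '>' with no header text")
            chunks = []
        else:
            if header is None:
                raise NotFastaError(
                    f"{path}: content before the first '>' definition line"
                )
            if ">" in line:
                raise MalformedRecordError(
                    f"record {header!r}: '>' inside a sequence line"
                )
            chunks.append(line)
    if header is None:
        raise NotFastaError(f"{path}: no '>' definition line found")
    flush()

    if saw_blank_interior:
        logger.warning("%s: blank interior line(s) skipped", path)

    dialect = SINGLE_LINE if max_chunks <= 1 else MULTI_LINE
    return FastaDocument(tuple(records), dialect)


def write_fasta_single_line(doc: FastaDocument, path: Path | str) -> Path:
    """Write ``>header\\nsequence\\n`` per record, in order, LF endings.

    Re-reading the written file yields an equal document with dialect
    ``single_line``. Refuses to overwrite an existing file.
    """
    path = Path(path)
    if path.exists():
        raise AlreadyExistsError(f"output already exists: {path}")
    if not path.parent.is_dir():
        raise OutputPathError(f"not a writable directory: {path.parent}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for record in doc.records:
            fh.write(f">{record.header}\n{record.sequence}\n")
    return path


def degap(doc: FastaDocument) -> FastaDocument:
    """Delete every ``-`` from every sequence; headers and order unchanged.

    Only ``-`` is treated as a gap (``.`` and ``~`` are left alone). A
    record that is entirely gaps raises :class:`EmptyAfterDegapError`,
    since an empty sequence is not uploadable.
    """
    out = []
    for record in doc.records:
        seq = record.sequence.replace(GAP, "")
        if not seq:
            raise EmptyAfterDegapError(
                f"record {record.header!r} is gap-only: nothing left after degapping"
            )
        out.append(FastaRecord(record.header, seq))
    return FastaDocument(tuple(out), doc.source_dialect)


def rank_seq(doc: FastaDocument) -> FastaDocument:
    """Reorder records from shortest to longest sequence (stable on ties)."""
    ordered = sorted(doc.records, key=lambda r: len(r.sequence))
    return FastaDocument(tuple(ordered), doc.source_dialect)


def head_derep(doc: FastaDocument) -> FastaDocument:
    """Keep the first record for each distinct header, in first-seen order.

    Headers are compared verbatim (the whole definition line after ``>``,
    trailing whitespace trimmed) — specimen-ID headers may carry meaningful
    pipes and spaces, so no tokenization is applied.
    """
    seen: set[str] = set()
    out = []
    for record in doc.records:
        if record.header not in seen:
            seen.add(record.header)
            out.append(record)
    return FastaDocument(tuple(out), doc.source_dialect)


def seq_derep(doc: FastaDocument) -> FastaDocument:
    """Keep the first record for each distinct sequence, in first-seen order.

    Sequences are keyed case-insensitively (soft-masked lowercase is a
    formatting artifact, not a haplotype difference) but gaps are kept as
    written — run :func:`degap` first to collapse across alignments. The
    number of output records is the file's distinct-sequence (haplotype)
    count.
    """
    seen: set[str] = set()
    out = []
    for record in doc.records:
        key = record.sequence.upper()
        if key not in seen:
            seen.add(key)
            out.append(record)
    return FastaDocument(tuple(out), doc.source_dialect)


def multi_to_single_fasta(
    in_path: Path | str,
    out_dir: Path | str,
    run_date: datetime.date | None = None,
) -> Path:
    """Convert a (possibly multi-line) FASTA to single-line format.

    Writes ``YYYYMMDD_multi_to_single_fasta.fas`` into ``out_dir``; record
    count, headers, and concatenated sequences are identical to the input.
    """
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise OutputPathError(f"not a writable directory: {out_dir}")
    doc = read_fasta(in_path)
    out = out_dir / naming.render("multi_to_single_fasta", run_date)
    return write_fasta_single_line(doc, out)
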
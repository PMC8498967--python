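"""Readers and writers for repeat-annotation inputs.

Two tabular dialects are supported for per-hit repeat annotations:

``out``
    The classic whitespace-aligned masker output: three header lines
    followed by one row per hit (score, divergence, deletion/insertion
    percentages, query coordinates, strand, matching repeat, repeat
    class/family, repeat coordinates, hit ID, and an optional trailing
    ``*`` marking a hit overlapped by a higher-scoring one).

``tsv``
    An equivalent named-header, tab-delimited table (UTF-8, ``#``
    comment lines permitted) that round-trips every field exactly.

Coordinates are 1-based inclusive on disk (the ``.out`` convention) and
converted to 0-based half-open in memory; writers convert back.  The
strand token ``C`` (complement) maps to ``-``.

Repeat libraries are plain FASTA; classification is taken from the
``name#classification`` convention in the record id, falling back to the
description line.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classification import ClassificationLabel, parse_classification_label
from .errors import RepeatParseError

__all__ = [
    "RepeatRecord",
    "LibraryEntry",
    "parse_repeatmasker_out",
    "write_repeatmasker_out",
    "read_records",
    "write_records",
    "read_library",
    "write_library",
    "read_tsv",
    "write_tsv",
]


@dataclass(frozen=True)
class RepeatRecord:
    """One masked hit: a stretch of a query read/contig attributed to a
    repeat consensus.  The atom of the abundance and landscape stages.

    ``start``/``end`` are 0-based half-open on the query; ``pct_div`` is
    the percent divergence of the hit from its consensus, stored exactly
    as reported by the upstream tool (no substitution-model correction).
    """

    query_id: str
    query_len: int
    start: int
    end: int
    consensus_id: str
    classification: ClassificationLabel
    pct_div: float
    score: float = 0.0
    strand: str = "+"
    overlap_flag: bool = False

    def __post_init__(self):
        if not (0 <= self.start < self.end <= self.query_len):
            raise ValueError(
                f"bad coordinates [{self.start},{self.end}) on "
                f"{self.query_id!r} of length {self.query_len}"
            )
        if not (0.0 <= self.pct_div <= 100.0):
            raise ValueError(f"pct_div {self.pct_div} outside [0, 100]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def span(self) -> int:
        """Masked length in bp."""
        return self.end - self.start


@dataclass(frozen=True)
class LibraryEntry:
    """One repeat-library consensus sequence."""

    id: str
    classification: ClassificationLabel
    length: int
    sequence: str | None = None

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("library entry length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != declared {self.length}"
            )


_OUT_HEADER = (
    "   SW  perc perc perc  query     position in query    matching"
    "          repeat             position in repeat\n"
    "score  div. del. ins.  sequence  begin end   (left)   repeat"
    "            class/family     begin  end    (left)  ID\n"
    "\n"
)

_TSV_COLUMNS = [
    "query_id",
    "query_len",
    "q_start",
    "q_end",
    "strand",
    "consensus_id",
    "classification",
    "pct_div",
    "score",
    "overlap_flag",
]


def _as_lines(stream: str | TextIO) -> Iterator[str]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    return iter(stream)


def _parse_out_row(tokens: list[str], lineno: int) -> RepeatRecord:
    overlap = tokens[-1] == "*"
    if overlap:
        tokens = tokens[:-1]
    if len(tokens) < 14:
        raise RepeatParseError(
            f"expected >= 14 columns in .out row, got {len(tokens)}", lineno
        )
    try:
        score = float(tokens[0])
        pct_div = float(tokens[1])
        query_id = tokens[4]
        q_begin = int(tokens[5])
        q_end = int(tokens[6])
        q_left = int(tokens[7].strip("()"))
    except ValueError as exc:
        raise RepeatParseError(f"non-numeric field in .out row ({exc})", lineno)
    strand = tokens[8]
    if strand == "C":
        strand = "-"
    elif strand != "+":
        raise RepeatParseError(f"bad strand token {strand!r}", lineno)
    consensus_id = tokens[9]
    class_label = tokens[10]
    query_len = q_end + q_left
    try:
        return RepeatRecord(
            query_id=query_id,
            query_len=query_len,
            start=q_begin - 1,
            end=q_end,
            consensus_id=consensus_id,
            classification=parse_classification_label(class_label),
            pct_div=pct_div,
            score=score,
            strand=strand,
            overlap_flag=overlap,
        )
    except ValueError as exc:
        raise RepeatParseError(str(exc), lineno)


def parse_repeatmasker_out(
    stream: str | TextIO, dialect: str = "out"
) -> list[RepeatRecord]:
    """Parse per-hit repeat annotations from a ``.out``-style file or an
    equivalent TSV.

    Records carrying the trailing ``*`` (hit overlapped by a
    higher-scoring hit) are retained with ``overlap_flag=True``;
    downstream stages decide whether to exclude them.
    """
    if dialect == "tsv":
        return _parse_records_tsv(stream)
    if dialect != "out":
        raise RepeatParseError(f"unknown dialect {dialect!r}")

    records: list[RepeatRecord] = []
    for lineno, line in enumerate(_as_lines(stream), start=1):
        if lineno <= 3:  # fixed header block
            continue
        tokens = line.split()
        if not tokens:
            continue
        records.append(_parse_out_row(tokens, lineno))
    return records


def write_repeatmasker_out(records: Iterable[RepeatRecord], stream: TextIO) -> None:
    """Write records in the ``.out`` dialect (1-based inclusive coordinates,
    strand '-' rendered as ``C``)."""
    stream.write(_OUT_HEADER)
    for i, r in enumerate(records, start=1):
        strand = "C" if r.strand == "-" else "+"
        left = r.query_len - r.end
        row = (
            f"{r.score:5.0f} {r.pct_div:5.2f}  0.0  0.0  {r.query_id}  "
            f"{r.start + 1} {r.end} ({left}) {strand} {r.consensus_id}  "
            f"{r.classification.render()}  1 {r.span} (0) {i}"
        )
        if r.overlap_flag:
            row += " *"
        stream.write(row + "\n")


def _parse_records_tsv(stream: str | TextIO) -> list[RepeatRecord]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", comment="#")
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise RepeatParseError(f"TSV missing columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                RepeatRecord(
                    query_id=str(row.query_id),
                    query_len=int(row.query_len),
                    start=int(row.q_start) - 1,
                    end=int(row.q_end),
                    consensus_id=str(row.consensus_id),
                    classification=parse_classification_label(
                        str(row.classification)
                    ),
                    pct_div=float(row.pct_div),
                    score=float(row.score),
                    strand=str(row.strand),
                    overlap_flag=bool(row.overlap_flag),
                )
            )
        except ValueError as exc:
            raise RepeatParseError(str(exc), i)
    return records


def read_records(path, dialect: str | None = None) -> list[RepeatRecord]:
    """Read hit records from a file path, inferring the dialect from the
    extension (``.out`` vs anything else = TSV) unless given."""
    path = str(path)
    if dialect is None:
        dialect = "out" if path.endswith(".out") else "tsv"
    with open(path, encoding="utf-8") as fh:
        return parse_repeatmasker_out(fh, dialect=dialect)


def write_records(records: Iterable[RepeatRecord], path, dialect: str | None = None):
    """Write hit records to a path in the chosen (or extension-inferred)
    dialect."""
    path = str(path)
    if dialect is None:
        dialect = "out" if path.endswith(".out") else "tsv"
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "out":
            write_repeatmasker_out(records, fh)
            return
        rows = [
            {
                "query_id": r.query_id,
                "query_len": r.query_len,
                "q_start": r.start + 1,
                "q_end": r.end,
                "strand": r.strand,
                "consensus_id": r.consensus_id,
                "classification": r.classification.render(),
                "pct_div": r.pct_div,
                "score": r.score,
                "overlap_flag": r.overlap_flag,
            }
            for r in records
        ]
        pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(fh, sep="\t", index=False)


def read_library(path, with_sequences: bool = True) -> list[LibraryEntry]:
    """Read a repeat library FASTA.

    Classification is parsed from the ``id#classification`` naming
    convention; ids without a ``#`` suffix fall back to the first
    whitespace-separated description token, else unclassified.
    """
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "#" in rec.id:
            ident, label = rec.id.split("#", 1)
        else:
            ident = rec.id
            desc = rec.description.split(maxsplit=1)
            label = desc[1].split()[0] if len(desc) > 1 else "Unknown"
        seq = str(rec.seq).upper()
        entries.append(
            LibraryEntry(
                id=ident,
                classification=parse_classification_label(label),
                length=len(seq),
                sequence=seq if with_sequences else None,
            )
        )
    return entries


def write_library(entries: Iterable[LibraryEntry], path) -> None:
    """Write a repeat library FASTA using the ``id#classification``
    convention."""
    records = []
    for e in entries:
        if e.sequence is None:
            raise ValueError(f"library entry {e.id!r} has no sequence to write")
        records.append(
            SeqRecord(
                Seq(e.sequence), id=f"{e.id}#{e.classification.render()}",
                description="",
            )
        )
    SeqIO.write(records, str(path), "fasta")


def read_tsv(path_or_stream) -> pd.DataFrame:
    """Read a named-header, tab-delimited table (UTF-8; ``#`` comments)."""
    return pd.read_csv(path_or_stream, sep="\t", comment="#")


def write_tsv(df: pd.DataFrame, path_or_stream, comment: str | None = None) -> None:
    """Write a DataFrame as a tab-delimited table, optionally preceded by a
    ``#``-prefixed comment line."""
    if isinstance(path_or_stream, (str, bytes)) or hasattr(path_or_stream, "__fspath__"):
        with open(path_or_stream, "w", encoding="utf-8") as fh:
            write_tsv(df, fh, comment=comment)
        return
    if comment:
        for line in comment.splitlines():
            path_or_stream.write(f"# {line}\n")
    df.to_csv(path_or_stream, sep="\t", index=False)
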
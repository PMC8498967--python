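"""Per-taxon genome-fraction tables from masked-hit records.

The survey unit is the set of sequenced bases (reads, not an assembly):
``total_bp`` is supplied by the caller as the summed read length, and a
taxon's abundance is the fraction of those surveyed bases masked by
hits attributed to it.  Overlapping hits on the same query are resolved
per base — the highest-scoring hit wins each base, ties broken by input
order — so every surveyed base is counted at most once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError, UsageError
from .repeatio import RepeatRecord, read_tsv, write_tsv

__all__ = [
    "AbundanceTable",
    "masked_fraction_table",
    "unknown_differential",
    "coverage_estimate",
    "class_ratio",
]

LEVELS = ("class", "order", "superfamily")


@dataclass
class AbundanceTable:
    """Masked-bp abundance rolled up to one classification level.

    ``table`` has columns ``taxon``, ``masked_bp``, ``pct_genome`` with
    ``pct_genome = 100 * masked_bp / total_bp`` and the conservation
    guarantee that summed ``masked_bp`` never exceeds ``total_bp``.
    """

    table: pd.DataFrame
    total_bp: int
    level: str
    weighting: str = "bp"

    def __post_init__(self):
        if self.total_bp <= 0:
            raise DomainError("total_bp must be positive")
        if self.weighting == "bp" and self.table["masked_bp"].sum() > self.total_bp:
            raise DomainError("masked bp exceeds surveyed bp")

    @property
    def masked_bp(self) -> int:
        return int(self.table["masked_bp"].sum())

    @property
    def pct_masked(self) -> float:
        return 100.0 * self.masked_bp / self.total_bp

    def pct_of(self, taxon: str) -> float:
        rows = self.table.loc[self.table["taxon"] == taxon, "pct_genome"]
        return float(rows.iloc[0]) if len(rows) else 0.0

    def to_tsv(self, path_or_stream) -> None:
        write_tsv(
            self.table,
            path_or_stream,
            comment=(
                f"level={self.level} total_bp={self.total_bp} "
                f"weighting={self.weighting}"
            ),
        )

    @classmethod
    def from_tsv(cls, path, total_bp: int, level: str, weighting: str = "bp"):
        return cls(read_tsv(path), total_bp=total_bp, level=level,
                   weighting=weighting)


def _resolved_spans(hits: Sequence[tuple[int, RepeatRecord]]) -> Iterable[
    tuple[RepeatRecord, int]
]:
    """Assign each base of a query to at most one hit.

    Hits are taken in priority order (score desc, then input order) and
    each contributes only the bases not already claimed.  Yields
    ``(record, bp_won)``.
    """
    taken: list[tuple[int, int]] = []  # disjoint, sorted claimed intervals
    for _, rec in sorted(hits, key=lambda t: (-t[1].score, t[0])):
        won = 0
        cursor = rec.start
        for ts, te in sorted(taken):
            if te <= cursor:
                continue
            if ts >= rec.end:
                break
            if ts > cursor:
                won += min(ts, rec.end) - cursor
            cursor = max(cursor, te)
            if cursor >= rec.end:
                break
        if cursor < rec.end:
            won += rec.end - cursor
        if won:
            taken = _merge(taken, (rec.start, rec.end))
            yield rec, won


def _merge(intervals: list[tuple[int, int]], new: tuple[int, int]):
    out = []
    ns, ne = new
    for s, e in sorted(intervals + [new]):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def masked_fraction_table(
    records: Sequence[RepeatRecord],
    total_bp: int,
    level: str = "superfamily",
    weighting: str = "bp",
) -> AbundanceTable:
    """Roll masked hits up to per-taxon abundance.

    ``weighting='bp'`` (default, matching percent-of-genome reporting)
    counts overlap-resolved masked bases; ``weighting='records'`` counts
    hits instead, with no overlap resolution.  Mass with no
    classification at the requested level is reported under
    ``unclassified`` (or ``<order>/unclassified`` for order-only labels
    at superfamily level).
    """
    if level not in LEVELS:
        raise UsageError(f"level must be one of {LEVELS}, got {level!r}")
    if weighting not in ("bp", "records"):
        raise UsageError(f"weighting must be 'bp' or 'records', got {weighting!r}")
    if total_bp <= 0:
        raise DomainError("total_bp must be positive")

    mass: dict[str, int] = {}
    if weighting == "records":
        for rec in records:
            taxon = rec.classification.render_level(level)
            mass[taxon] = mass.get(taxon, 0) + 1
    else:
        by_query: dict[str, list[tuple[int, RepeatRecord]]] = {}
        for i, rec in enumerate(records):
            by_query.setdefault(rec.query_id, []).append((i, rec))
        for hits in by_query.values():
            for rec, won in _resolved_spans(hits):
                taxon = rec.classification.render_level(level)
                mass[taxon] = mass.get(taxon, 0) + won

    df = pd.DataFrame(
        sorted(mass.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["taxon", "masked_bp"],
    )
    if df.empty:
        df = pd.DataFrame(columns=["taxon", "masked_bp"])
    df["pct_genome"] = 100.0 * df["masked_bp"] / total_bp
    return AbundanceTable(df, total_bp=total_bp, level=level, weighting=weighting)


def unknown_differential(
    pct_with_unknown: float, pct_without_unknown: float
) -> float:
    """Genome share attributable to unknown repeats: the difference
    between the masked percentage with and without the unknown-repeat
    contigs in the library."""
    if not (0.0 <= pct_without_unknown <= pct_with_unknown <= 100.0):
        raise DomainError(
            "expected 0 <= pct_without_unknown <= pct_with_unknown <= 100 "
            f"(got {pct_with_unknown}, {pct_without_unknown}); "
            "check run labelling"
        )
    return pct_with_unknown - pct_without_unknown


def coverage_estimate(total_read_bp: float, genome_size_bp: float) -> float:
    """Sequencing coverage of a shotgun survey: surveyed bp over haploid
    genome size."""
    if total_read_bp <= 0 or genome_size_bp <= 0:
        raise DomainError("read bp and genome size must be positive")
    return total_read_bp / genome_size_bp


def class_ratio(
    table: AbundanceTable, numerator: str = "ClassI", denominator: str = "ClassII"
) -> float:
    """Fold difference between two taxa's genome percentages (typically
    retrotransposons vs DNA transposons at class level)."""
    num = table.pct_of(numerator)
    den = table.pct_of(denominator)
    if den <= 0:
        raise DomainError(f"denominator taxon {denominator!r} absent or zero")
    if num <= 0:
        raise DomainError(f"numerator taxon {numerator!r} absent or zero")
    return num / den
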
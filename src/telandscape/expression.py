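"""TE annotation and expression summaries for an assembled transcriptome.

Transcriptome contigs are annotated from three evidence tracks:
protein-level TE hits (autonomous elements, which encode transposition
machinery), nucleotide-level hits against a library of non-autonomous
elements (SINE/MITE/TRIM/LARD derivatives, accepted only under the
80/80/80 rule: alignment > 80 bp, > 80% identity, > 80% library-contig
coverage), and host-gene annotations.  Each contig with expression at
or above a TPM floor receives exactly one category; contigs with
conflicting autonomous and non-autonomous TE evidence are filtered out.

Expression is summarised as summed TPM per category and per TE
superfamily, and the abundance-expression relationship is tested with
Pearson's correlation on log-transformed genome percentage vs summed
TPM per superfamily.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .abundance import AbundanceTable
from .classification import is_ambiguous_taxon
from .errors import DomainError, TELandscapeError

__all__ = [
    "ProteinTEHit",
    "NuclTEHit",
    "GeneAnnotation",
    "TranscriptRecord",
    "CategoryAssignment",
    "eighty_rule_filter",
    "categorize_transcripts",
    "expression_summary",
    "abundance_expression_correlation",
    "te_gene_geometry",
]

CATEGORIES = (
    "autonomous_te",
    "non_autonomous_te",
    "te_gene",
    "gene",
    "unknown",
    "filtered_conflict",
)


@dataclass(frozen=True)
class ProteinTEHit:
    """A protein-level (translated) hit to a TE protein database."""

    superfamily: str
    e_value: float
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    frame: int | None = None


@dataclass(frozen=True)
class NuclTEHit:
    """A nucleotide-level hit to a non-autonomous repeat-library contig."""

    library_id: str
    aln_len: int
    identity: float
    library_coverage: float

    def __post_init__(self):
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.library_coverage <= 1.0):
            raise DomainError("identity and coverage must be fractions in [0,1]")


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    start: int | None = None
    end: int | None = None
    strand: str | None = None


@dataclass
class TranscriptRecord:
    contig_id: str
    tpm: float
    protein_te_hits: list[ProteinTEHit] = field(default_factory=list)
    nucl_te_hits: list[NuclTEHit] = field(default_factory=list)
    gene_annotations: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self):
        if self.tpm < 0:
            raise DomainError("TPM must be non-negative")

    def best_protein_hit(self) -> ProteinTEHit | None:
        """Lowest e-value; ties broken by input order."""
        best = None
        for hit in self.protein_te_hits:
            if best is None or hit.e_value < best.e_value:
                best = hit
        return best


@dataclass(frozen=True)
class CategoryAssignment:
    contig_id: str
    category: str


def eighty_rule_filter(hit: NuclTEHit) -> bool:
    """The 80/80/80 acceptance rule for non-autonomous TE annotation:
    overlap > 80 bp, > 80% identity, covering > 80% of the library
    contig.  All comparisons are strict."""
    return hit.aln_len > 80 and hit.identity > 0.80 and hit.library_coverage > 0.80


def categorize_transcripts(
    records: Sequence[TranscriptRecord], min_tpm: float = 0.01
) -> tuple[list[CategoryAssignment], dict[str, int]]:
    """Assign each sufficiently expressed contig to one category.

    Contigs below ``min_tpm`` are dropped before categorization.
    Decision order: conflicting autonomous + (passing) non-autonomous
    evidence is filtered out; TE + gene evidence makes a te_gene; then
    autonomous TE, non-autonomous TE, gene, unknown.
    """
    assignments = []
    summary = {c: 0 for c in CATEGORIES}
    summary["dropped_low_tpm"] = 0
    for rec in records:
        if rec.tpm < min_tpm:
            summary["dropped_low_tpm"] += 1
            continue
        has_protein = bool(rec.protein_te_hits)
        has_nucl = any(eighty_rule_filter(h) for h in rec.nucl_te_hits)
        has_gene = bool(rec.gene_annotations)
        if has_protein and has_nucl:
            category = "filtered_conflict"
        elif has_protein and has_gene:
            category = "te_gene"
        elif has_nucl and has_gene:
            category = "te_gene"
        elif has_protein:
            category = "autonomous_te"
        elif has_nucl:
            category = "non_autonomous_te"
        elif has_gene:
            category = "gene"
        else:
            category = "unknown"
        summary[category] += 1
        assignments.append(CategoryAssignment(rec.contig_id, category))
    return assignments, summary


def expression_summary(
    assignments: Sequence[CategoryAssignment],
    records: Sequence[TranscriptRecord],
    denominator: str = "million",
) -> dict:
    """Summed TPM per category and per TE superfamily.

    Fractions of the transcriptome use the TPM normalization constant
    10^6 by default (``denominator='million'``); ``'observed'`` divides
    by the summed TPM of the retained contigs instead.  Per-superfamily
    sums take each autonomous contig's best (lowest e-value) protein
    hit.
    """
    by_id = {r.contig_id: r for r in records}
    cat_tpm = {c: 0.0 for c in CATEGORIES}
    sf_tpm: dict[str, float] = {}
    total = 0.0
    for a in assignments:
        rec = by_id[a.contig_id]
        cat_tpm[a.category] += rec.tpm
        total += rec.tpm
        if a.category == "autonomous_te":
            best = rec.best_protein_hit()
            if best is not None:
                sf_tpm[best.superfamily] = (
                    sf_tpm.get(best.superfamily, 0.0) + rec.tpm
                )
    if denominator == "million":
        denom = 1e6
    elif denominator == "observed":
        denom = total if total > 0 else np.nan
    else:
        raise DomainError(f"denominator must be million|observed, got {denominator!r}")
    return {
        "category_tpm": cat_tpm,
        "category_fraction": {c: v / denom for c, v in cat_tpm.items()},
        "superfamily_tpm": dict(
            sorted(sf_tpm.items(), key=lambda kv: -kv[1])
        ),
        "total_tpm": total,
    }


def abundance_expression_correlation(
    genome_table: AbundanceTable | Mapping[str, float],
    expr_sums: Mapping[str, float],
    log_base: float = 10.0,
) -> tuple[float, float, int]:
    """Pearson correlation between log genome percentage and log summed
    TPM across TE superfamilies.

    Superfamilies absent or non-positive in either table are excluded
    (the returned n reports how many remain; fewer than 3 is an error).
    The correlation is invariant to the log base.
    """
    if isinstance(genome_table, AbundanceTable):
        df = genome_table.table
        genome = {
            str(t): float(p)
            for t, p in zip(df["taxon"], df["pct_genome"])
            if not is_ambiguous_taxon(str(t))
        }
    else:
        genome = dict(genome_table)
    shared = [
        sf
        for sf in genome
        if genome[sf] > 0 and expr_sums.get(sf, 0.0) > 0
    ]
    n = len(shared)
    if n < 3:
        raise DomainError(
            f"need >= 3 superfamilies with positive abundance and "
            f"expression, got {n}"
        )
    lg = np.log(log_base)
    x = np.log([genome[sf] for sf in shared]) / lg
    y = np.log([expr_sums[sf] for sf in shared]) / lg
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def te_gene_geometry(record: TranscriptRecord) -> dict:
    """Spatial relationship of a co-transcribed TE/gene pair.

    Requires exactly one TE annotation (protein hit) with coordinates
    and one gene annotation with coordinates on the same contig.
    Position is upstream (TE entirely before the gene), downstream, or
    overlapping; strand is same/opposite; frame is assessed only for
    same-strand non-overlapping pairs, as whether the TE-to-gene start
    offset is a multiple of 3.
    """
    te = record.best_protein_hit()
    if te is None or not record.gene_annotations:
        raise TELandscapeError("record must carry one TE and one gene annotation")
    gene = record.gene_annotations[0]
    for obj, what in ((te, "TE"), (gene, "gene")):
        if obj.start is None or obj.end is None:
            raise TELandscapeError(f"{what} annotation lacks coordinates")

    if te.end <= gene.start:
        position = "upstream"
    elif te.start >= gene.end:
        position = "downstream"
    else:
        position = "overlapping"

    if te.strand is None or gene.strand is None:
        strand = "unknown"
    else:
        strand = "same" if te.strand == gene.strand else "opposite"

    if position == "overlapping" or strand != "same":
        frame = "n/a"
    else:
        frame = "in" if (gene.start - te.start) % 3 == 0 else "out"
    return {"position": position, "strand": strand, "frame": frame}
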
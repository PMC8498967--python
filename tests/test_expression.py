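"""Transcriptome categorization, expression summaries, and the
abundance-expression correlation."""

import numpy as np
import pytest

from telandscape.errors import DomainError
from telandscape.expression import (
    CATEGORIES,
    GeneAnnotation,
    NuclTEHit,
    ProteinTEHit,
    TranscriptRecord,
    abundance_expression_correlation,
    categorize_transcripts,
    eighty_rule_filter,
    expression_summary,
    te_gene_geometry,
)
from telandscape.synthetic_data import noise_sd_for_target_r, simulate_expression


def protein(sf="DIRS/DIRS", e=1e-30, **kw):
    return ProteinTEHit(superfamily=sf, e_value=e, **kw)


def nucl(aln_len=100, identity=0.9, coverage=0.9):
    return NuclTEHit("lib1", aln_len, identity, coverage)


class TestEightyRule:
    @pytest.mark.parametrize(
        "aln_len, identity, coverage, expected",
        [
            (100, 0.85, 0.90, True),
            (80, 0.95, 0.95, False),   # strict > on length
            (81, 0.80, 0.95, False),   # strict > on identity
            (81, 0.95, 0.80, False),   # strict > on coverage
            (300, 0.95, 0.60, False),
            (81, 0.81, 0.81, True),
        ],
    )
    def test_all_three_thresholds_strict(self, aln_len, identity, coverage,
                                         expected):
        assert eighty_rule_filter(nucl(aln_len, identity, coverage)) is expected


class TestCategorize:
    def test_decision_order(self):
        records = [
            TranscriptRecord("auto", 1.0, protein_te_hits=[protein()]),
            TranscriptRecord("nonauto", 1.0, nucl_te_hits=[nucl()]),
            TranscriptRecord("conflict", 1.0, protein_te_hits=[protein()],
                             nucl_te_hits=[nucl()]),
            TranscriptRecord("tegene", 1.0, protein_te_hits=[protein()],
                             gene_annotations=[GeneAnnotation("g1")]),
            TranscriptRecord("tegene2", 1.0, nucl_te_hits=[nucl()],
                             gene_annotations=[GeneAnnotation("g2")]),
            TranscriptRecord("gene", 1.0,
                             gene_annotations=[GeneAnnotation("g3")]),
            TranscriptRecord("mystery", 1.0),
        ]
        assignments, summary = categorize_transcripts(records)
        got = {a.contig_id: a.category for a in assignments}
        assert got == {
            "auto": "autonomous_te",
            "nonauto": "non_autonomous_te",
            "conflict": "filtered_conflict",
            "tegene": "te_gene",
            "tegene2": "te_gene",
            "gene": "gene",
            "mystery": "unknown",
        }
        assert summary["te_gene"] == 2

    def test_failing_nucl_hit_does_not_conflict(self):
        rec = TranscriptRecord(
            "c", 1.0, protein_te_hits=[protein()],
            nucl_te_hits=[nucl(aln_len=50)],
        )
        (assignment,), _ = categorize_transcripts([rec])
        assert assignment.category == "autonomous_te"

    def test_low_tpm_dropped_before_categorization(self):
        records = [
            TranscriptRecord("low", 0.005, protein_te_hits=[protein()]),
            TranscriptRecord("kept", 0.01, protein_te_hits=[protein()]),
        ]
        assignments, summary = categorize_transcripts(records)
        assert [a.contig_id for a in assignments] == ["kept"]
        assert summary["dropped_low_tpm"] == 1

    def test_categories_partition_retained_contigs(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(100):
            records.append(
                TranscriptRecord(
                    f"c{i}", float(rng.uniform(0, 1)),
                    protein_te_hits=[protein()] if rng.random() < 0.4 else [],
                    nucl_te_hits=[nucl()] if rng.random() < 0.2 else [],
                    gene_annotations=(
                        [GeneAnnotation("g")] if rng.random() < 0.3 else []
                    ),
                )
            )
        assignments, summary = categorize_transcripts(records, min_tpm=0.2)
        n_categorized = sum(summary[c] for c in CATEGORIES)
        assert n_categorized == len(assignments)
        assert n_categorized + summary["dropped_low_tpm"] == len(records)


class TestExpressionSummary:
    def test_superfamily_sums_use_best_protein_hit(self):
        records = [
            TranscriptRecord("c1", 10.0, protein_te_hits=[
                protein("DIRS/DIRS", 1e-40), protein("LINE/L1", 1e-10)]),
            TranscriptRecord("c2", 5.0, protein_te_hits=[protein("DIRS/DIRS")]),
            TranscriptRecord("c3", 2.0, protein_te_hits=[protein("TIR/hAT")]),
        ]
        assignments, _ = categorize_transcripts(records)
        summary = expression_summary(assignments, records)
        assert summary["superfamily_tpm"] == {
            "DIRS/DIRS": 15.0, "TIR/hAT": 2.0
        }

    def test_fraction_uses_million_denominator(self):
        records = [TranscriptRecord("c", 131_793.0,
                                    protein_te_hits=[protein()])]
        assignments, _ = categorize_transcripts(records)
        summary = expression_summary(assignments, records)
        assert 100 * summary["category_fraction"]["autonomous_te"] == \
            pytest.approx(13.2, abs=0.05)

    def test_fractions_sum_to_total_over_million(self):
        rng = np.random.default_rng(1)
        records = [
            TranscriptRecord(f"c{i}", float(rng.uniform(0.1, 100)),
                             protein_te_hits=[protein()] if i % 2 else [])
            for i in range(20)
        ]
        assignments, _ = categorize_transcripts(records)
        summary = expression_summary(assignments, records)
        assert sum(summary["category_fraction"].values()) == pytest.approx(
            summary["total_tpm"] / 1e6
        )

    def test_empty(self):
        summary = expression_summary([], [])
        assert summary["total_tpm"] == 0.0
        assert summary["superfamily_tpm"] == {}


class TestCorrelation:
    def test_exact_log_linear_is_one(self):
        genome = {"a": 1.0, "b": 10.0, "c": 100.0}
        expr = {"a": 2.0, "b": 20.0, "c": 200.0}
        r, p, n = abundance_expression_correlation(genome, expr)
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_exact_inverse_log_linear_is_minus_one(self):
        genome = {"a": 1.0, "b": 10.0, "c": 100.0}
        expr = {"a": 200.0, "b": 20.0, "c": 2.0}
        r, _, _ = abundance_expression_correlation(genome, expr)
        assert r == pytest.approx(-1.0)

    def test_log_base_invariance(self):
        rng = np.random.default_rng(2)
        genome = {f"s{i}": float(rng.uniform(0.01, 30)) for i in range(12)}
        expr = {f"s{i}": float(rng.uniform(1, 1e4)) for i in range(12)}
        r10, _, _ = abundance_expression_correlation(genome, expr, log_base=10)
        re_, _, _ = abundance_expression_correlation(genome, expr,
                                                     log_base=np.e)
        assert r10 == pytest.approx(re_, abs=1e-12)

    def test_missing_superfamilies_excluded(self):
        genome = {"a": 1.0, "b": 10.0, "c": 100.0, "d": 5.0}
        expr = {"a": 2.0, "b": 20.0, "c": 200.0, "e": 7.0}
        _, _, n = abundance_expression_correlation(genome, expr)
        assert n == 3
        with pytest.raises(DomainError):
            abundance_expression_correlation({"a": 1.0, "b": 2.0},
                                             {"a": 1.0, "b": 2.0})

    def test_synthetic_coupling_recovers_target_r(self):
        """Sample r over seeded replicates stays inside the 95% CI of the
        configured population correlation."""
        rng = np.random.default_rng(3)
        genome = {f"s{i}": float(10 ** rng.uniform(-2, 1.5))
                  for i in range(25)}
        target = 0.88
        noise = noise_sd_for_target_r(genome, slope=1.0, target_r=target)
        rs = []
        for seed in range(100):
            expr = simulate_expression(genome, slope=1.0, noise_sd=noise,
                                       seed=seed)
            r, _, _ = abundance_expression_correlation(genome, expr)
            rs.append(r)
        # Fisher-z 95% CI for a single estimate at n=25
        z_se = 1.0 / np.sqrt(25 - 3)
        z_target = np.arctanh(target)
        lo, hi = np.tanh(z_target - 1.96 * z_se), np.tanh(z_target + 1.96 * z_se)
        assert lo < np.mean(rs) < hi
        assert abs(np.mean(rs) - target) < 0.02


class TestTEGeneGeometry:
    def _record(self, te_coords, te_strand, gene_coords, gene_strand):
        return TranscriptRecord(
            "c", 1.0,
            protein_te_hits=[protein(start=te_coords[0], end=te_coords[1],
                                     strand=te_strand)],
            gene_annotations=[GeneAnnotation("g", start=gene_coords[0],
                                             end=gene_coords[1],
                                             strand=gene_strand)],
        )

    def test_upstream_same_strand_in_frame(self):
        # start offset 499 - 100 = 399, a multiple of 3
        geometry = te_gene_geometry(
            self._record((100, 400), "+", (499, 900), "+")
        )
        assert geometry == {"position": "upstream", "strand": "same",
                            "frame": "in"}

    def test_downstream_opposite_strand(self):
        geometry = te_gene_geometry(
            self._record((600, 900), "-", (100, 500), "+")
        )
        assert geometry == {"position": "downstream", "strand": "opposite",
                            "frame": "n/a"}

    def test_overlapping(self):
        geometry = te_gene_geometry(
            self._record((100, 600), "+", (400, 900), "+")
        )
        assert geometry["position"] == "overlapping"
        assert geometry["frame"] == "n/a"

    def test_out_of_frame_offset(self):
        geometry = te_gene_geometry(
            self._record((100, 400), "+", (501, 900), "+")
        )
        assert geometry["frame"] == "out"
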
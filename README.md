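# telandscape

Transposable-element (TE) landscape characterization from low-coverage
genome skims.

Most of the variation in eukaryotic genome size is TE load, and in rare
lineages — giant amphibian genomes above 10 Gb are the canonical case —
the TE community has expanded enormously. Assembling such genomes is
often infeasible, but a shallow shotgun survey masked against a repeat
library already contains the three community properties that models of
TE/host dynamics make predictions about: **abundance** (what fraction of
the genome each TE taxon occupies), **diversity** (how evenly that mass
is spread across taxa), and **activity** (which taxa are still
amplifying). `telandscape` computes all three, plus two companion
analyses: an estimate of ectopic recombination-mediated deletion from
read depth over element terminals, and the coupling between genomic TE
abundance and somatic TE expression.

## What it computes

Given per-hit repeat annotations (RepeatMasker-style `.out` or an
equivalent TSV) of reads totalling `B` surveyed bp:

* **Abundance** — per-taxon masked fractions with deterministic per-base
  overlap resolution (highest score wins), rolled up to class, order, or
  superfamily (`abundance.masked_fraction_table`).
* **Diversity** — the TE community as a proportion vector
  *P₁ … P_S* over superfamilies, summarised by the Shannon index
  *H′ = −Σ Pᵢ ln Pᵢ* (nats) and the Gini-Simpson index
  *D = 1 − Σ Pᵢ²*, with a Spearman test of genome size against either
  index across genomes (`diversity`).
* **Activity** — per-superfamily divergence landscapes (1% bins of each
  read's distance to its closest consensus) and a deterministic
  shape/activity classifier: a superfamily is called active when recent
  mass (< 1% diverged) exceeds a floor and the landscape is monotonically
  decreasing, unimodal right-skewed, J-shaped, or bimodal with a recent
  mode (`landscape`).
* **Deletion** — the total-terminal-to-internal depth ratio (TT:I) of
  LTR/DIRS-like elements. With no ectopic recombination the
  length-normalized depths of terminal and internal sequence are equal
  (TT:I = 1:1); solo terminals left by recombination push the ratio to
  1 + s/2 for s solo terminals per intact element, which
  `structure.solo_fraction_estimate` inverts (`structure`).
* **Expression** — transcriptome categorization (autonomous TEs by
  protein hits, non-autonomous TEs under the strict 80 bp / 80% identity
  / 80% coverage rule, TE/gene co-transcripts, genes), summed TPM per
  category and superfamily, and Pearson's r between log genome
  percentage and log summed TPM (`expression`).
* **Family richness** — deterministic greedy clustering at the 80%
  identity threshold that operationally defines TE families
  (`famcluster`).
* **Synthetic truth** — a fully seeded generator of genomes with known
  TE composition and amplification history, reads, oracle mask records,
  solo-terminal element populations, and abundance-coupled expression
  tables, so every stage is testable without external data
  (`synthetic_data`).

## Worked example

Simulate a desk-scale skim of a DIRS-dominated community (400 kb genome,
8× coverage) and characterize it:

```bash
telandscape simulate --seed 7 --out-dir demo --genome-len 400000 \
    --coverage 8 --read-len 150
telandscape abundance --records demo/mask.tsv --total-bp 3199950 \
    --out demo/abundance.tsv
head -6 demo/abundance.tsv
```

```
# level=superfamily total_bp=3199950 weighting=bp
taxon	masked_bp	pct_genome
DIRS/DIRS	960116	30.00409381396584
LINE/Jockey	648414	20.26325411334552
LINE/L1	97072	3.0335473991781123
LTR/ERV	59568	1.861529086391975
```

The two dominant superfamilies were planted at 30.2% and 20.6% of the
genome; the read survey recovers them to within sampling error.

```bash
telandscape diversity --composition demo/abundance.tsv
```

```
shannon	1.378100
gini_simpson	0.644735
richness	11
```

A community of 11 superfamilies dominated by two of them: the Shannon
index sits far below its ln 11 ≈ 2.40 maximum and the Gini-Simpson
index says two random TE bases differ in superfamily only 64% of the
time — low evenness despite full richness.

```bash
telandscape tti --alignments demo/alignments.tsv \
    --models demo/element_models.tsv --min-aligned-len 20 --min-aligned-len 50
```

```
superfamily	min_aligned_len	mean_tti	n_contigs	n_undefined
DIRS/DIRS	20	0.9678955891575117	1	0
DIRS/DIRS	50	0.9212951668269734	1	0
```

The bundle's element population was simulated with zero solo terminals,
and the TT:I ratio is accordingly ≈ 1:1 at the permissive threshold; at
stricter alignment-length floors the short (150 bp) terminals lose their
clipped end reads first and the ratio drifts down — the stringency
sensitivity the sweep is designed to expose.

`telandscape run-all --config config.yaml --out-dir report/` chains the
stages and writes per-stage TSVs plus a `summary.txt` embedding the
config and seed.

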
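# Methods

This note records the models, parameter choices, and numerical
conventions behind each stage, and what the synthetic-data tests do and
do not demonstrate about real data.

## Survey model and units

The survey unit is the sequenced read set, not an assembly: low-coverage
shotgun reads are assumed to sample the genome uniformly and
independently, so the fraction of surveyed bases masked by a TE taxon is
an unbiased estimate of its genome fraction. `total_bp` (the summed read
length) is always supplied by the caller rather than inferred, and all
percentages are bp-weighted ("percent of surveyed bp"); a record-count
weighting exists as an option but is never the default. Coordinates are
1-based inclusive in files (the `.out` convention) and 0-based half-open
in memory; writers convert back.

## Overlap resolution (abundance)

Overlapping hits on a query are resolved per base: hits are taken in
order of decreasing alignment score, ties broken by input order, and
each hit claims only bases not already claimed. This makes the rollup a
partition of the masked bases — summed `masked_bp` is identical at
class, order, and superfamily level — and is verified exactly against a
per-base bitmask oracle in the tests. Hits flagged as overlapped by the
upstream masker (`*`) are retained by the parser; exclusion is a
downstream policy decision, not a parsing one.

## Classification

Labels follow the hierarchical class/order/superfamily system
(retrotransposons = Class I: LTR, DIRS, PLE, LINE, SINE; DNA
transposons = Class II: TIR, Helitron, Maverick, Crypton), with explicit
tags for the non-autonomous derivative groups (SINE, MITE, TRIM, LARD).
Tool-dialect tokens (`DNA/hAT`, `RC/Helitron`, `TcMar-Tc1`, …) are
normalized through an editable YAML alias table shipped as package
data. Unparseable labels degrade to *unclassified* and are logged,
never raised: in a skim survey, unknown repeats are data, not errors.

## Diversity indices

Shannon *H′ = −Σ Pᵢ ln Pᵢ* is computed in natural log (nats), exactly as
the formula is conventionally printed; Gini-Simpson is *1 − Σ Pᵢ²*. The
default proportion vector uses classified mass only: unclassified and
order-only rows are dropped before renormalization, with an
`include_unclassified` switch for sensitivity. Family-level evenness is
generally unavailable from short reads (multi-mapping), so the
80%-identity cluster count from `famcluster` is reported as a
richness-only proxy at that level. Cross-genome comparisons use Spearman
rank correlation of genome size against each index (two-sided p), since
no linearity assumption is defensible across orders of magnitude of
genome size.

## Divergence landscapes and activity calling

Each query contributes its least-divergent hit (ties: higher score, then
input order) — divergence to the *closest* consensus, since a
superfamily's library contains many family/subfamily consensus
sequences. Divergence is used exactly as reported by the upstream tool;
no substitution-model (e.g. Kimura) correction is applied, and the
stored value is labelled raw.

Histograms use half-open 1% bins. The activity classifier is a
deterministic procedure replacing by-eye shape calls:

1. normalize the bins and smooth with a centered moving average
   (default width 3, truncated at the edges);
2. `recent_fraction` = raw mass below 1% divergence;
3. modes = local maxima of the smoothed profile (edge bins eligible)
   at ≥ 10% of the global maximum;
4. shape rules, in order: *monotonically decreasing* (every smoothed bin
   ≤ 1.05× its predecessor, mode at bin 0); single mode → *J-shaped*
   (mode in the top decile of occupied bins, left-concentrated mass) or
   *unimodal right-skewed* (mass at and right of the mode exceeds the
   left mass), with a *recent spike* annotation when the raw first bin
   exceeds twice its smoothed value; two or more modes with one in the
   first two bins → *bimodal recent*;
5. active ⇔ `recent_fraction` > 0.5% **and** the shape is one of the
   accumulation-consistent shapes. A single-mode profile without recent
   mass is *unimodal inactive*.

The 0.5% recent-mass floor makes "presence of sequences < 1% diverged"
robust to a handful of spurious low-divergence hits; window, prominence,
and tolerance are exposed as parameters. Superfamilies below 0.005% of
the genome are excluded from assessment (too few masked reads for a
stable histogram). Exact shape labels on marginal profiles are not
guaranteed — e.g. a right-skewed profile with a strong recent spike may
be labelled bimodal-recent rather than unimodal-with-spike; both are in
the active set, and the tested guarantee is the activity dichotomy
(≥ 95% accuracy on scenario-labelled synthetic landscapes).

## TT:I estimation

Element models carry terminal intervals and an internal interval
conservatively bounded by the first and last protein-domain hits.
Terminal repeats are located by self-comparison of the contig's two end
windows: exact 11-mer seeds, ungapped extension at match +1 / mismatch
−2 with X-drop 20, identity and length floors (defaults 80%, 50 bp);
for DIRS-like elements the tail window is reverse-complemented so
inverted terminal repeats seed directly. This finder trades gapped
sensitivity for determinism; heavily indel-diverged terminals can be
missed, which matches its role of *confirming* terminal structure.

Depth over a region is summed overlap-bp of retained alignments divided
by region length: a read contributes fractionally to a region it partly
covers, and boundary-spanning reads count on both sides. This is the
only convention under which "hits scaled by region length" yields
exactly 1:1 for intact elements under uniform coverage. Both terminals
pool into a single "total terminal" class. Stringency is expressed as a
minimum aligned length in bp (default sweep 20/30/40/50), the observable
that mapper score thresholds manipulate; per-contig ratios are averaged
unweighted, and contigs with zero internal coverage are excluded and
counted. Under uniform sampling from `n_full` intact copies and
`n_solo` solo terminals the expectation is TT:I = 1 + n_solo/(2·n_full);
`solo_fraction_estimate` inverts this, flooring at 0 for ratios below 1.
DIRS elements are handled identically to direct-repeat elements at the
depth stage; no correction is attempted for their partial internal
deletion products, so their estimates are conservative.

## Expression integration

Autonomous TEs are those with protein-level hits to a TE protein
database; non-autonomous annotations are accepted only under the strict
80/80/80 rule (> 80 bp, > 80% identity, > 80% library-contig coverage —
all strict inequalities). Contigs below TPM 0.01 are dropped first;
contigs with conflicting autonomous and non-autonomous evidence are
filtered out; TE + gene evidence yields the te_gene category.
Transcriptome fractions divide by the TPM normalization constant 10⁶ by
default (an `observed` denominator is available). The
abundance-expression test is Pearson's r on log₁₀ genome percentage vs
log₁₀ summed TPM per superfamily (r is log-base invariant; both
transforms are tested equal), over superfamilies positive in both
tables, with n reported and n < 3 an error. "In frame" for TE/gene
co-transcripts is defined operationally as same strand and a TE-to-gene
start offset divisible by 3; overlapping or opposite-strand pairs are
n/a. Curation overrides (e.g. manually reclassified spurious
annotations) are out of scope of the categorizer itself.

## Family clustering

Longest-first greedy clustering with representative-only comparison:
deterministic, O(n·k) in alignments, intended for desk-scale inputs (up
to a few thousand sequences). Identity is matches over the shorter
sequence's length from a global alignment (match +1, mismatch −1, gap
open −5, gap extend −1), a dialect approximating common clustering
tools; cluster counts therefore approximate, not reproduce, any
specific external tool's output.

## Synthetic data: what it does and does not emulate

The generator plants TE copies (substitution-only mutation of random
family consensus sequences; the realized substitution count is the
recorded truth divergence) at uniform non-overlapping positions in
i.i.d. background of configurable GC, samples error-free fixed-length
reads uniformly, and emits oracle mask records from the true
coordinates. Five divergence scenarios define amplification histories:
exponential mean 2% (recent burst), truncated normal 8% ± 2% (past
peak), truncated normal 15% ± 2% (inactive), a ½-½ mixture of the first
two (bimodal), and exponential mean 5% (steady accumulation). Under
these parameters the expected recent fractions are ≈ 39%, 0.02%, ~0%,
~20%, and 18% respectively, so the scenario-level activity truth is
active for recent-burst/monotonic/bimodal and inactive for
past-peak/inactive-old.

Element populations for TT:I embed every copy in flanking sequence, so
reads may overhang a copy and are clipped to it — the sampling scheme
under which consensus depth is exactly uniform in expectation and the
deletion-free null is exactly 1:1.

Expression tables are log-linearly coupled to abundance with Gaussian
noise in log₁₀ TPM, rescaled to a fixed total. Two calibrations exist:
`noise_sd_for_target_r` solves the closed-form *population* correlation,
and `calibrate_noise_sd` bisects against a seeded Monte-Carlo estimate
of the *expected sample* correlation, which at community sizes of a few
dozen superfamilies sits visibly (~+0.01) above the population value;
the second is the right tool when a simulated community should
reproduce a reported sample correlation in expectation.

Deliberately not emulated: sequencing error, indels (available but off
by default so reported and true divergence coincide), TE nesting and
fragmentation, insertion-site preference, and alignment heuristics (the
oracle masker uses true coordinates). Passing tests therefore
demonstrate the correctness of the downstream statistics under clean
annotations, not robustness to masking or mapping artifacts.

## Problem sizes and determinism

All generators take an integer seed and are byte-reproducible. Test and
acceptance runs use desk-scale inputs chosen to keep every stage's
sampling error well inside its asserted tolerance: genomes of 0.1–1 Mb,
coverages of 8–20×, 150–250 bp reads, element populations of 60–100
intact copies, 200 scenario landscapes of 300 copies, and 20-replicate
nulls. The TT:I null and correlation reproductions report means over
seeded replicates with the replicate count alongside.

## Known limitations

* The landscape classifier's shape taxonomy is heuristic on profiles
  with few masked reads; abundance floors, not the classifier, are the
  defense against unstable histograms of rare superfamilies.
* TT:I for inverted-repeat (DIRS-like) elements ignores their partial
  internal deletion products; true deletion levels are underestimated
  in proportion to that incompleteness.
* Greedy representative clustering can split a family whose members
  chain through > 20% pairwise divergence; counts are an upper bound on
  such fixtures.
* Single-sample expression supports point estimates and correlation
  only; no replication-dependent inference is offered.
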
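"""Synthetic TE genomes, reads, element populations, and expression tables.

Every pipeline stage can be exercised without external data: this module
fabricates a genome of known TE composition, shotgun reads from it,
masker-style hit records derived from the true insertion coordinates, a
terminal/internal element population with a configurable solo-terminal
fraction, and an expression table log-linearly coupled to genomic
abundance with tunable noise.  All generators are fully seeded and
byte-reproducible; the ground truth of each simulation is returned
alongside the artifacts so recovery can be asserted.

Per-copy divergences follow one of five amplification-history scenarios:

``recent_burst``
    exponential with mean 2% — a young, expanding superfamily.
``past_peak``
    normal(8%, 2%) truncated at 0 — a burst that ended long ago; almost
    no copies below 1% divergence.
``inactive_old``
    normal(15%, 2%) truncated at 0 — an ancient, extinct superfamily.
``bimodal``
    an equal mixture of the first two — an old burst plus renewed
    activity.
``monotonic``
    exponential with mean 5% — steady accumulation, still at its peak.

Mutation is substitution-only by default, so a copy's true divergence
and the divergence a masker would report coincide; reads are error-free
(sequencing error would blur the landscape and is orthogonal to the
statistics computed downstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .classification import parse_classification_label
from .errors import DomainError, UsageError
from .landscape import DivergenceLandscape
from .repeatio import RepeatRecord
from .structure import ElementModel, ReadAlignment

__all__ = [
    "SuperfamilySpec",
    "CommunitySpec",
    "TECopy",
    "SimRead",
    "CommunityTruth",
    "SCENARIOS",
    "scenario_expected_active",
    "sample_divergences",
    "scenario_landscape",
    "simulate_genome_and_reads",
    "emit_mask_records",
    "simulate_element_population",
    "simulate_expression",
    "noise_sd_for_target_r",
    "calibrate_noise_sd",
    "default_community_spec",
]

SCENARIOS = ("recent_burst", "past_peak", "inactive_old", "bimodal", "monotonic")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MAX_DIV = 45.0  # divergence cap, %


@dataclass(frozen=True)
class SuperfamilySpec:
    """Target composition and history for one simulated superfamily."""

    name: str
    classification: str
    target_genome_fraction: float
    landscape_scenario: str = "monotonic"
    n_families: int = 3
    consensus_len: int = 2000

    def __post_init__(self):
        if self.landscape_scenario not in SCENARIOS:
            raise UsageError(
                f"unknown scenario {self.landscape_scenario!r}; "
                f"expected one of {SCENARIOS}"
            )
        if not (0.0 <= self.target_genome_fraction <= 1.0):
            raise UsageError("target_genome_fraction must be in [0,1]")
        if self.consensus_len < 1 or self.n_families < 1:
            raise UsageError("consensus_len and n_families must be positive")


@dataclass(frozen=True)
class CommunitySpec:
    superfamilies: tuple[SuperfamilySpec, ...]
    genome_len: int = 1_000_000
    background_gc: float = 0.40

    def __post_init__(self):
        total = sum(sf.target_genome_fraction for sf in self.superfamilies)
        if total > 1.0:
            raise UsageError(f"target fractions sum to {total:.3f} > 1")
        if self.genome_len < 1:
            raise UsageError("genome_len must be positive")


@dataclass(frozen=True)
class TECopy:
    superfamily: str
    classification: str
    family: int
    start: int  # genome coordinates, 0-based half-open
    end: int
    divergence: float  # realized substitution divergence, %


@dataclass(frozen=True)
class SimRead:
    read_id: str
    start: int
    end: int


@dataclass
class CommunityTruth:
    """Ground truth of a simulated genome: what recovery is measured
    against."""

    spec: CommunitySpec
    copies: list[TECopy]
    realized_fractions: dict[str, float]
    expression_coupling: dict | None = None

    def divergence_histogram(
        self, superfamily: str, bin_width: float = 1.0
    ) -> DivergenceLandscape:
        """Length-ignoring histogram of true per-copy divergences."""
        divs = np.array(
            [c.divergence for c in self.copies if c.superfamily == superfamily]
        )
        if len(divs) == 0:
            raise DomainError(f"no copies of {superfamily!r} in truth")
        n_bins = int(divs.max() // bin_width) + 1
        edges = np.arange(n_bins + 1) * bin_width
        edges[-1] = np.nextafter(edges[-1], np.inf)
        counts, _ = np.histogram(divs, bins=edges)
        return DivergenceLandscape(
            superfamily=superfamily, bins=counts, bin_width=bin_width
        )


def sample_divergences(
    scenario: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-copy divergences (%) for one scenario, truncated to
    [0, 45]."""
    if scenario == "recent_burst":
        d = rng.exponential(2.0, n)
    elif scenario == "monotonic":
        d = rng.exponential(5.0, n)
    elif scenario == "past_peak":
        d = _truncated_normal(8.0, 2.0, n, rng)
    elif scenario == "inactive_old":
        d = _truncated_normal(15.0, 2.0, n, rng)
    elif scenario == "bimodal":
        recent = rng.exponential(2.0, n)
        old = _truncated_normal(8.0, 2.0, n, rng)
        pick = rng.random(n) < 0.5
        d = np.where(pick, recent, old)
    else:
        raise UsageError(f"unknown scenario {scenario!r}")
    return np.minimum(d, _MAX_DIV)


def _truncated_normal(mean, sd, n, rng):
    d = rng.normal(mean, sd, n)
    while np.any(d < 0):  # rejection; negligible mass at these parameters
        bad = d < 0
        d[bad] = rng.normal(mean, sd, bad.sum())
    return d


def scenario_expected_active(scenario: str) -> bool:
    """Whether a scenario's divergence distribution places enough mass
    below 1% divergence to count as ongoing activity.

    recent_burst, monotonic and bimodal all leave 15%-40% of copies under
    1% diverged; past_peak and inactive_old leave essentially none
    (normal tails 3.5 and 7 standard deviations out).
    """
    return scenario in ("recent_burst", "monotonic", "bimodal")


def scenario_landscape(
    scenario: str, n_copies: int, seed: int, bin_width: float = 1.0,
    superfamily: str | None = None,
) -> DivergenceLandscape:
    """A divergence landscape drawn directly from a scenario — the
    cheapest way to exercise the activity classifier at scale."""
    rng = np.random.default_rng(seed)
    d = sample_divergences(scenario, n_copies, rng)
    n_bins = int(d.max() // bin_width) + 1
    edges = np.arange(n_bins + 1) * bin_width
    edges[-1] = np.nextafter(edges[-1], np.inf)
    counts, _ = np.histogram(d, bins=edges)
    return DivergenceLandscape(
        superfamily=superfamily or scenario, bins=counts, bin_width=bin_width
    )


# ---------------------------------------------------------------------------
# genome + reads


def _random_codes(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    at, gcp = (1.0 - gc) / 2.0, gc / 2.0
    return rng.choice(4, size=n, p=[at, gcp, gcp, at]).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _mutate(consensus: np.ndarray, pct: float, rng: np.random.Generator):
    """Substitute a fixed number of positions so realized divergence is
    exactly n_sub/len."""
    n = len(consensus)
    n_sub = int(round(pct / 100.0 * n))
    n_sub = min(n_sub, n)
    copy = consensus.copy()
    if n_sub:
        pos = rng.choice(n, size=n_sub, replace=False)
        copy[pos] = (copy[pos] + rng.integers(1, 4, size=n_sub)) % 4
    return copy, 100.0 * n_sub / n


def simulate_genome_and_reads(
    spec: CommunitySpec,
    coverage: float = 10.0,
    read_len: int = 250,
    seed: int = 0,
) -> tuple[str, CommunityTruth, list[SimRead]]:
    """Simulate a genome of known TE composition and shotgun reads.

    Background sequence is i.i.d. at the spec's GC; each superfamily
    gets ``n_families`` random consensus sequences, and copies (mutated
    per the superfamily's scenario) are inserted at uniform positions
    without overlap.  Reads of fixed length are sampled uniformly.
    """
    if coverage <= 0:
        raise UsageError("coverage must be positive")
    if read_len >= spec.genome_len:
        raise UsageError("read_len must be smaller than genome_len")
    rng = np.random.default_rng(seed)

    copies_meta = []  # (sf_spec, family, codes, realized_div)
    for sf in spec.superfamilies:
        consensi = [
            _random_codes(sf.consensus_len, spec.background_gc, rng)
            for _ in range(sf.n_families)
        ]
        n_copies = int(round(sf.target_genome_fraction * spec.genome_len
                             / sf.consensus_len))
        if n_copies == 0 and sf.target_genome_fraction > 0:
            n_copies = 1
        families = rng.integers(0, sf.n_families, size=n_copies)
        divs = sample_divergences(sf.landscape_scenario, n_copies, rng)
        for fam, d in zip(families, divs):
            codes, realized = _mutate(consensi[fam], float(d), rng)
            copies_meta.append((sf, int(fam), codes, realized))

    te_bp = sum(len(c[2]) for c in copies_meta)
    bg_len = spec.genome_len - te_bp
    if bg_len < 0:
        raise DomainError(
            f"TE fractions infeasible: {te_bp} bp of copies exceed "
            f"genome_len {spec.genome_len}"
        )
    background = _random_codes(bg_len, spec.background_gc, rng)

    order = rng.permutation(len(copies_meta))
    offsets = np.sort(rng.integers(0, bg_len + 1, size=len(copies_meta)))

    pieces = []
    copies: list[TECopy] = []
    cursor = 0  # background consumed
    genome_pos = 0
    for offset, idx in zip(offsets, order):
        sf, fam, codes, realized = copies_meta[idx]
        pieces.append(background[cursor:offset])
        genome_pos += offset - cursor
        cursor = offset
        pieces.append(codes)
        copies.append(
            TECopy(
                superfamily=sf.name,
                classification=sf.classification,
                family=fam,
                start=genome_pos,
                end=genome_pos + len(codes),
                divergence=realized,
            )
        )
        genome_pos += len(codes)
    pieces.append(background[cursor:])
    genome_codes = (
        np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
    )
    assert len(genome_codes) == spec.genome_len

    realized_fractions = {}
    for sf in spec.superfamilies:
        bp = sum(c.end - c.start for c in copies if c.superfamily == sf.name)
        realized_fractions[sf.name] = bp / spec.genome_len

    n_reads = int(round(coverage * spec.genome_len / read_len))
    starts = rng.integers(0, spec.genome_len - read_len + 1, size=n_reads)
    width = len(str(max(n_reads, 1)))
    reads = [
        SimRead(read_id=f"read{i:0{width}d}", start=int(s), end=int(s) + read_len)
        for i, s in enumerate(starts)
    ]
    truth = CommunityTruth(
        spec=spec, copies=copies, realized_fractions=realized_fractions
    )
    return _codes_to_str(genome_codes), truth, reads


def emit_mask_records(
    truth: CommunityTruth,
    reads: Sequence[SimRead],
    min_overlap: int = 20,
) -> list[RepeatRecord]:
    """Oracle masker: convert true insertion coordinates into per-hit
    records.

    Each read overlapping a TE copy by at least ``min_overlap`` bp
    yields one record whose divergence is the copy's true substitution
    divergence; reads wholly in background yield none.  The hit score is
    the overlap length, so overlap resolution downstream prefers the
    larger contribution.
    """
    tree = IntervalTree()
    for i, c in enumerate(truth.copies):
        tree[c.start:c.end] = i
    records = []
    for read in reads:
        read_len = read.end - read.start
        for iv in sorted(tree.overlap(read.start, read.end)):
            copy = truth.copies[iv.data]
            ov_start = max(read.start, copy.start)
            ov_end = min(read.end, copy.end)
            if ov_end - ov_start < min_overlap:
                continue
            records.append(
                RepeatRecord(
                    query_id=read.read_id,
                    query_len=read_len,
                    start=ov_start - read.start,
                    end=ov_end - read.start,
                    consensus_id=f"{copy.superfamily}-fam{copy.family}",
                    classification=parse_classification_label(
                        copy.classification
                    ),
                    pct_div=round(copy.divergence, 2),
                    score=float(ov_end - ov_start),
                    strand="+",
                )
            )
    return records


# ---------------------------------------------------------------------------
# element population (TT:I fixture)


def simulate_element_population(
    n_full: int,
    n_solo: int,
    terminal_len: int = 150,
    internal_len: int = 5586,
    coverage: float = 20.0,
    read_len: int = 150,
    seed: int = 0,
    contig_id: str = "consensus",
    superfamily: str = "",
    mode: str = "direct",
) -> tuple[ElementModel, list[ReadAlignment]]:
    """Reads drawn uniformly from a population of intact two-terminal
    elements and solo terminals, mapped onto one consensus model.

    Each population copy is embedded in flanking sequence, so reads may
    overhang its boundary and are clipped to the element — exactly how
    local alignment against a consensus treats reads from real flanked
    insertions.  Under this sampling the expected per-bp depth is
    uniform and TT:I = 1 + n_solo / (2 * n_full).  The geometry defaults
    are a DIRS-like element (150 bp terminals, 5586 bp internal).
    """
    if n_full < 1 or n_solo < 0:
        raise UsageError("need n_full >= 1 and n_solo >= 0")
    if terminal_len < 1 or internal_len < 1 or read_len < 1:
        raise UsageError("lengths must be positive")
    if read_len >= internal_len:
        raise UsageError("read_len must be below internal_len")
    rng = np.random.default_rng(seed)
    full_len = 2 * terminal_len + internal_len
    model = ElementModel(
        contig_id=contig_id,
        contig_len=full_len,
        mode=mode,
        terminals=[(0, terminal_len), (terminal_len + internal_len, full_len)],
        internal=(terminal_len, terminal_len + internal_len),
        superfamily=superfamily,
    )
    population_bp = n_full * full_len + n_solo * terminal_len
    n_reads = int(round(coverage * population_bp / read_len))
    # eligible start positions (any read overlapping the element by >= 1 bp)
    w_full = n_full * (full_len + read_len - 1)
    w_solo = n_solo * (terminal_len + read_len - 1)
    n_from_full = rng.binomial(n_reads, w_full / (w_full + w_solo)) \
        if w_solo else n_reads

    alignments: list[ReadAlignment] = []
    starts = rng.integers(-(read_len - 1), full_len, size=n_from_full)
    for i, s in enumerate(starts):
        a, b = max(int(s), 0), min(int(s) + read_len, full_len)
        alignments.append(
            ReadAlignment(f"full{i}", contig_id, a, b)
        )
    n_from_solo = n_reads - n_from_full
    if n_from_solo:
        starts = rng.integers(-(read_len - 1), terminal_len, size=n_from_solo)
        sides = rng.integers(0, 2, size=n_from_solo)
        for i, (s, side) in enumerate(zip(starts, sides)):
            a, b = max(int(s), 0), min(int(s) + read_len, terminal_len)
            shift = 0 if side == 0 else terminal_len + internal_len
            alignments.append(
                ReadAlignment(f"solo{i}", contig_id, a + shift, b + shift)
            )
    return model, alignments


# ---------------------------------------------------------------------------
# expression


def noise_sd_for_target_r(
    genome_fractions: Mapping[str, float], slope: float, target_r: float
) -> float:
    """Gaussian noise (in log10 TPM units) giving a population Pearson
    correlation of ``target_r`` for the given abundance design."""
    if not (0.0 < target_r <= 1.0):
        raise UsageError("target_r must be in (0, 1]")
    x = np.log10(np.array(list(genome_fractions.values()), dtype=float))
    sd_x = float(np.std(x))
    if sd_x == 0:
        raise DomainError("abundance values are all equal; r undefined")
    return abs(slope) * sd_x * np.sqrt(1.0 / target_r**2 - 1.0)


def calibrate_noise_sd(
    genome_fractions: Mapping[str, float],
    slope: float,
    target_r: float,
    n_replicates: int = 2000,
    calibration_seed: int = 987_654,
    tol: float = 1e-4,
) -> float:
    """Noise level whose *expected sample* Pearson correlation equals
    ``target_r`` for this abundance design.

    At small n the sample correlation of a fixed-design log-linear
    coupling sits slightly above the population value given by
    :func:`noise_sd_for_target_r`; this solves for the noise numerically
    (bisection against a seeded Monte-Carlo estimate of E[r]), so a
    simulated community reproduces a reported correlation in
    expectation, not merely in population.
    """
    x = np.log10(np.array(list(genome_fractions.values()), dtype=float))
    x = slope * x
    xc = x - x.mean()
    sxx = float((xc**2).sum())
    rng = np.random.default_rng(calibration_seed)
    errors = rng.standard_normal((n_replicates, len(x)))

    def expected_r(noise_sd: float) -> float:
        y = x[None, :] + noise_sd * errors
        yc = y - y.mean(axis=1, keepdims=True)
        num = yc @ xc
        den = np.sqrt(sxx * (yc**2).sum(axis=1))
        return float(np.mean(num / den))

    lo = 0.0
    hi = 2.0 * noise_sd_for_target_r(genome_fractions, slope, target_r)
    while expected_r(hi) > target_r:
        hi *= 2.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if expected_r(mid) > target_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_expression(
    genome_fractions: Mapping[str, float],
    slope: float = 1.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    total_tpm: float = 1e6,
) -> dict[str, float]:
    """Per-superfamily TPM log-linearly coupled to genomic abundance.

    log10 TPM = slope * log10(fraction) + intercept + N(0, noise_sd),
    rescaled so the summed TPM over all simulated categories equals
    ``total_tpm``.  Correlation statistics are invariant to the
    rescaling.
    """
    if noise_sd < 0:
        raise UsageError("noise_sd must be >= 0")
    names = list(genome_fractions)
    fracs = np.array([genome_fractions[n] for n in names], dtype=float)
    if np.any(fracs <= 0):
        raise DomainError("genome fractions must be positive")
    rng = np.random.default_rng(seed)
    log_tpm = slope * np.log10(fracs) + rng.normal(0.0, noise_sd, len(fracs))
    tpm = np.power(10.0, log_tpm)
    tpm *= total_tpm / tpm.sum()
    return dict(zip(names, tpm))


# ---------------------------------------------------------------------------
# a desk-scale community preset


def default_community_spec(
    genome_len: int = 1_000_000, scale: float = 1.0
) -> CommunitySpec:
    """A community patterned on a DIRS-dominated giant amphibian genome:
    two hyper-abundant retrotransposon superfamilies over a long tail,
    mixing amplification-history scenarios.  ``scale`` multiplies every
    target fraction (the composition shape is what matters, not the
    absolute repeat load, for desk-scale runs)."""
    rows = [
        ("DIRS/DIRS", "DIRS/DIRS", 0.302, "past_peak"),
        ("LINE/Jockey", "LINE/Jockey", 0.206, "past_peak"),
        ("LINE/L1", "LINE/L1", 0.032, "monotonic"),
        ("LTR/ERV", "LTR/ERV", 0.018, "past_peak"),
        ("LINE/RTE", "LINE/RTE", 0.016, "past_peak"),
        ("LTR/Gypsy", "LTR/Gypsy", 0.0135, "monotonic"),
        ("TIR/hAT", "TIR/hAT", 0.0115, "recent_burst"),
        ("TIR/Tc1-Mariner", "TIR/Tc1-Mariner", 0.0059, "recent_burst"),
        ("TIR/CACTA", "TIR/CACTA", 0.0056, "monotonic"),
        ("SINE/5S", "SINE/5S", 0.004, "bimodal"),
        ("LTR/Retrovirus", "LTR/Retrovirus", 0.003, "inactive_old"),
    ]
    sfs = tuple(
        SuperfamilySpec(
            name=name,
            classification=label,
            target_genome_fraction=frac * scale,
            landscape_scenario=scenario,
            n_families=3,
            consensus_len=2000,
        )
        for name, label, frac, scenario in rows
    )
    return CommunitySpec(superfamilies=sfs, genome_len=genome_len)
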
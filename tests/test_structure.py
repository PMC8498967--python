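"""Element architecture and TT:I depth-ratio estimation."""

import numpy as np
import pytest

from telandscape.errors import (
    DomainError,
    StructureError,
    UndefinedRatioError,
    UsageError,
)
from telandscape.structure import (
    ElementModel,
    ReadAlignment,
    build_element_model,
    find_terminal_repeats,
    revcomp,
    solo_fraction_estimate,
    tti_ratio,
    tti_sweep,
    read_element_models,
    write_element_models,
    read_alignments,
    write_alignments,
)
from telandscape.synthetic_data import simulate_element_population

from conftest import mutate_dna, random_dna


class TestFindTerminalRepeats:
    def test_direct_repeat_pair_found(self):
        rng = np.random.default_rng(0)
        t = random_dna(120, rng)
        seq = t + random_dna(2000, rng) + t
        pairs = find_terminal_repeats(seq, "direct", end_window=300)
        assert pairs
        best = pairs[0]
        assert best.head == (0, 120)
        assert best.tail == (2120, 2240)
        assert best.identity == 1.0

    def test_inverted_repeat_pair_found(self):
        rng = np.random.default_rng(1)
        t = random_dna(120, rng)
        seq = t + random_dna(2000, rng) + revcomp(t)
        pairs = find_terminal_repeats(seq, "inverted", end_window=300)
        assert pairs
        head, tail = pairs[0].head, pairs[0].tail
        assert head[0] <= 0 + 5 and head[1] >= 115
        assert tail[1] >= 2235

    def test_diverged_repeat_found_above_identity_floor(self):
        rng = np.random.default_rng(2)
        t = random_dna(200, rng)
        seq = t + random_dna(1500, rng) + mutate_dna(t, 10, rng)  # 95% id
        pairs = find_terminal_repeats(seq, "direct", end_window=400,
                                      min_identity=0.9)
        assert pairs
        assert pairs[0].identity >= 0.9

    def test_random_sequence_has_no_repeats(self):
        rng = np.random.default_rng(3)
        seq = random_dna(5000, rng)
        # independent oracle: no 50 bp repeat can exist without a shared
        # exact 50-mer between the two end windows at 100% identity
        head, tail = seq[:1000], seq[-1000:]
        kmers = {head[i:i + 50] for i in range(len(head) - 49)}
        assert all(tail[j:j + 50] not in kmers for j in range(len(tail) - 49))
        assert find_terminal_repeats(seq, min_len=50) == []

    def test_non_iupac_rejected(self):
        with pytest.raises(DomainError):
            find_terminal_repeats("ACGT!!ACGT")


class TestBuildElementModel:
    def test_internal_bounded_by_domains(self):
        from telandscape.structure import TerminalPair

        pair = TerminalPair((0, 150), (5850, 6000), 1.0, 150.0, "direct")
        model = build_element_model(
            "c1", 6000, [pair], [(200, 4000), (2500, 5800)]
        )
        assert model.internal == (200, 5800)
        assert model.terminals == [(0, 150), (5850, 6000)]

    def test_terminal_clipped_to_internal(self):
        from telandscape.structure import TerminalPair

        pair = TerminalPair((0, 210), (5850, 6000), 1.0, 150.0, "direct")
        model = build_element_model("c1", 6000, [pair], [(200, 5800)])
        assert model.terminals[0] == (0, 200)

    def test_missing_inputs_error(self):
        from telandscape.structure import TerminalPair

        pair = TerminalPair((0, 150), (5850, 6000), 1.0, 150.0, "direct")
        with pytest.raises(DomainError):
            build_element_model("c1", 6000, [pair], [])
        with pytest.raises(DomainError):
            build_element_model("c1", 6000, [], [(200, 5800)])
        engulfed = TerminalPair((300, 450), (5000, 5150), 1.0, 150.0, "direct")
        with pytest.raises(StructureError):
            build_element_model("c1", 6000, [engulfed], [(0, 6000)])


def model_6kb():
    return ElementModel(
        contig_id="c",
        contig_len=6000,
        mode="direct",
        terminals=[(0, 150), (5850, 6000)],
        internal=(150, 5850),
    )


def brute_force_tti(alignments, model, min_aligned_len=0):
    """Per-base depth arrays, no interval arithmetic."""
    depth = np.zeros(model.contig_len)
    for a in alignments:
        if a.aligned_len >= min_aligned_len:
            depth[a.start:a.end] += 1
    term = np.concatenate([depth[s:e] for s, e in model.terminals])
    internal = depth[model.internal[0]:model.internal[1]]
    return term.mean() / internal.mean()


class TestTTIRatio:
    def test_uniform_depth_gives_unity(self):
        model = model_6kb()
        alignments = [
            ReadAlignment(f"r{i}", "c", s, min(s + 100, 6000))
            for i, s in enumerate(range(0, 6000, 10))
        ]
        # tile 10 extra reads at the very start to even out the edge ramp
        alignments += [
            ReadAlignment(f"e{i}", "c", 0, 100 - 10 * i) for i in range(10)
        ]
        res = tti_ratio(alignments, model)
        assert res.tti == pytest.approx(
            brute_force_tti(alignments, model), abs=1e-12
        )

    def test_known_depths(self):
        model = ElementModel("c", 30, "direct", [(0, 10), (20, 30)], (10, 20))
        alignments = (
            [ReadAlignment(f"t{i}", "c", 0, 10) for i in range(15)]
            + [ReadAlignment(f"u{i}", "c", 20, 30) for i in range(15)]
            + [ReadAlignment(f"i{i}", "c", 10, 20) for i in range(10)]
        )
        res = tti_ratio(alignments, model)
        assert res.depth_terminal == pytest.approx(15.0)
        assert res.depth_internal == pytest.approx(10.0)
        assert res.tti == pytest.approx(1.5)

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("min_len", [0, 40])
    def test_matches_per_base_brute_force(self, seed, min_len):
        rng = np.random.default_rng(seed)
        model = model_6kb()
        alignments = []
        for i in range(100):
            start = int(rng.integers(0, 5950))
            end = int(min(start + rng.integers(20, 150), 6000))
            alignments.append(ReadAlignment(f"r{i}", "c", start, end))
        res = tti_ratio(alignments, model, min_aligned_len=min_len)
        assert res.tti == pytest.approx(
            brute_force_tti(alignments, model, min_len), abs=1e-12
        )

    def test_boundary_read_contributes_to_both_sides(self):
        model = ElementModel("c", 30, "direct", [(0, 10), (20, 30)], (10, 20))
        res_err = None
        alignments = [ReadAlignment("r", "c", 5, 15)]
        try:
            tti_ratio(alignments, model)
        except UndefinedRatioError:
            res_err = "unreachable"
        assert res_err is None  # 5 bp fell in the internal region

    def test_no_internal_coverage_is_undefined(self):
        model = model_6kb()
        with pytest.raises(UndefinedRatioError):
            tti_ratio([ReadAlignment("r", "c", 0, 100)], model)

    def test_solo_free_null_within_three_se_of_unity(self):
        ttis = [
            tti_ratio(*reversed(simulate_element_population(
                n_full=60, n_solo=0, coverage=20, read_len=150, seed=seed
            ))).tti
            for seed in range(20)
        ]
        mean = np.mean(ttis)
        se = np.std(ttis, ddof=1) / np.sqrt(len(ttis))
        assert abs(mean - 1.0) < 3 * se + 1e-9

    def test_tti_monotone_in_solo_fraction(self):
        means = []
        for s in (0.0, 0.5, 1.0, 2.0):
            ttis = []
            for seed in range(8):
                model, alignments = simulate_element_population(
                    n_full=60, n_solo=int(60 * s), coverage=20,
                    read_len=150, seed=100 + seed,
                )
                ttis.append(tti_ratio(alignments, model).tti)
            means.append(np.mean(ttis))
        assert means == sorted(means)

    def test_solo_fraction_recovery(self):
        for s in (0.5, 1.0, 2.0):
            ttis = []
            for seed in range(10):
                model, alignments = simulate_element_population(
                    n_full=80, n_solo=int(80 * s), coverage=20,
                    read_len=150, seed=200 + seed,
                )
                ttis.append(tti_ratio(alignments, model).tti)
            estimate = solo_fraction_estimate(float(np.mean(ttis)))
            assert abs(estimate - s) / s < 0.15

    def test_solo_fraction_inversion(self):
        assert solo_fraction_estimate(1.0) == 0.0
        assert solo_fraction_estimate(1.5) == pytest.approx(1.0)
        assert solo_fraction_estimate(1.2) == pytest.approx(0.4)
        assert solo_fraction_estimate(0.8) == 0.0  # excess internal depth


class TestTTISweep:
    def test_single_contig_single_threshold(self):
        model, alignments = simulate_element_population(
            n_full=30, n_solo=0, coverage=10, read_len=150, seed=9
        )
        sweep = tti_sweep(alignments, [model], thresholds=[0])
        assert len(sweep) == 1
        assert sweep.iloc[0]["mean_tti"] == pytest.approx(
            tti_ratio(alignments, model).tti
        )

    def test_thresholds_that_discard_nothing_are_identical(self):
        model = model_6kb()
        alignments = [
            ReadAlignment(f"r{i}", "c", s, s + 100)
            for i, s in enumerate(range(0, 5900, 25))
        ]
        sweep = tti_sweep(alignments, [model], thresholds=[10, 50, 99])
        assert sweep["mean_tti"].nunique() == 1

    def test_shorter_terminals_more_sensitive_to_stringency(self):
        """Rising alignment-length floors deplete clipped end reads, and
        the depletion is proportionally larger for short terminals."""
        def sensitivity(terminal_len):
            deltas = []
            for seed in range(6):
                model, alignments = simulate_element_population(
                    n_full=60, n_solo=0, terminal_len=terminal_len,
                    internal_len=2000, coverage=30, read_len=150,
                    seed=300 + seed,
                )
                lo = tti_ratio(alignments, model, min_aligned_len=20).tti
                hi = tti_ratio(alignments, model, min_aligned_len=100).tti
                deltas.append(abs(hi - lo))
            return np.mean(deltas)

        assert sensitivity(150) > sensitivity(744)

    def test_empty_thresholds_rejected(self):
        with pytest.raises(UsageError):
            tti_sweep([], [model_6kb()], thresholds=[])


class TestTabularRoundTrips:
    def test_element_model_roundtrip(self, tmp_path):
        model = model_6kb()
        model.superfamily = "DIRS/DIRS"
        path = tmp_path / "models.tsv"
        write_element_models([model], path)
        (again,) = read_element_models(path)
        assert again.terminals == model.terminals
        assert again.internal == model.internal
        assert again.superfamily == "DIRS/DIRS"

    def test_alignment_roundtrip(self, tmp_path):
        alignments = [ReadAlignment("r1", "c", 5, 100),
                      ReadAlignment("r2", "c", 50, 70)]
        path = tmp_path / "alignments.tsv"
        write_alignments(alignments, path)
        assert read_alignments(path) == alignments
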
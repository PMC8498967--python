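"""Element architecture and ectopic-recombination-mediated deletion.

Retrotransposons flanked by terminal repeats (direct LTRs, or the
inverted terminal repeats of DIRS elements) are vulnerable to ectopic
(non-allelic homologous) recombination between their repeats.  A
recombination event deletes the internal sequence and one terminal,
leaving a *solo* terminal behind.  In a read survey this skews coverage:
with no deletion, terminal and internal sequence are equally deep, so
the length-normalized ratio of read depth over all terminal sequence to
depth over internal sequence (the TT:I ratio) is 1:1; solo terminals
push it above 1.  Under uniform sampling from a population of ``n_full``
intact copies and ``n_solo`` solo terminals the expectation is

    TT:I = 1 + n_solo / (2 * n_full)

which :func:`solo_fraction_estimate` inverts.

Terminal repeats are found by aligning a contig against itself
(seed-and-extend between its two ends); the internal region is bounded
by the first and last protein-domain hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    StructureError,
    UndefinedRatioError,
    UsageError,
)
from .repeatio import read_tsv, write_tsv

__all__ = [
    "TerminalPair",
    "ElementModel",
    "ReadAlignment",
    "TTIResult",
    "find_terminal_repeats",
    "build_element_model",
    "tti_ratio",
    "tti_sweep",
    "solo_fraction_estimate",
    "read_element_models",
    "write_element_models",
    "read_alignments",
    "write_alignments",
]

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn",
                            "TGCAYRMKVBHDNtgcayrmkvbhdn")
_IUPAC = set("ACGTRYSWKMBDHVN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TerminalPair:
    """A self-alignment between the two ends of a contig.

    ``head`` and ``tail`` are 0-based half-open intervals on the contig
    (the tail interval is given in forward coordinates even when the
    alignment was against the reverse complement)."""

    head: tuple[int, int]
    tail: tuple[int, int]
    identity: float
    score: float
    mode: str

    @property
    def length(self) -> int:
        return self.head[1] - self.head[0]


@dataclass
class ElementModel:
    """A contig's terminal/internal architecture."""

    contig_id: str
    contig_len: int
    mode: str  # direct | inverted
    terminals: list[tuple[int, int]]
    internal: tuple[int, int]
    superfamily: str = ""

    def __post_init__(self):
        if self.mode not in ("direct", "inverted"):
            raise UsageError(f"mode must be direct|inverted, got {self.mode!r}")
        ivs = sorted(self.terminals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if e1 > s2:
                raise StructureError("terminal intervals overlap")
        for s, e in self.terminals:
            if max(s, self.internal[0]) < min(e, self.internal[1]):
                raise StructureError("terminal overlaps internal region")

    @property
    def terminal_len(self) -> int:
        return sum(e - s for s, e in self.terminals)

    @property
    def internal_len(self) -> int:
        return self.internal[1] - self.internal[0]


@dataclass(frozen=True)
class ReadAlignment:
    """One read mapped onto a contig (0-based half-open)."""

    read_id: str
    contig_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise DomainError(
                f"empty alignment [{self.start},{self.end}) for {self.read_id!r}"
            )

    @property
    def aligned_len(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TTIResult:
    contig_id: str
    depth_terminal: float
    depth_internal: float
    tti: float
    min_aligned_len: int
    n_alignments_used: int


def _extend(a: str, b: str, i: int, j: int, direction: int, xdrop: int,
            match: int = 1, mismatch: int = -2) -> tuple[int, int]:
    """Ungapped X-drop extension.  Returns (best offset count, best score
    gain) moving ``direction`` (+1 right from i,j inclusive / -1 left from
    i-1,j-1)."""
    best = score = 0
    best_k = 0
    k = 0
    while True:
        if direction > 0:
            ia, jb = i + k, j + k
            if ia >= len(a) or jb >= len(b):
                break
        else:
            ia, jb = i - 1 - k, j - 1 - k
            if ia < 0 or jb < 0:
                break
        score += match if a[ia] == b[jb] else mismatch
        k += 1
        if score > best:
            best, best_k = score, k
        elif best - score > xdrop:
            break
    return best_k, best


def find_terminal_repeats(
    seq: str,
    mode: str = "direct",
    min_len: int = 50,
    min_identity: float = 0.80,
    end_window: int = 1000,
    k: int = 11,
    xdrop: int = 20,
) -> list[TerminalPair]:
    """Locate terminal repeats by aligning a contig against itself.

    Exact ``k``-mer seeds between the first and last ``end_window`` bp
    are extended without gaps (match +1, mismatch -2, X-drop ``xdrop``).
    For ``mode='inverted'`` the tail window is reverse-complemented
    before seeding, so inverted terminal repeats seed as direct matches.
    Pairs with alignment length >= ``min_len`` and identity >=
    ``min_identity`` are returned best-scoring first.
    """
    seq = seq.upper()
    if set(seq) - _IUPAC:
        raise DomainError("sequence contains non-IUPAC characters")
    if mode not in ("direct", "inverted"):
        raise UsageError(f"mode must be direct|inverted, got {mode!r}")
    n = len(seq)
    w = min(end_window, n)
    head = seq[:w]
    tail_start = max(0, n - w)
    tail_fwd = seq[tail_start:]
    target = revcomp(tail_fwd) if mode == "inverted" else tail_fwd
    if len(head) < k or len(target) < k:
        return []

    seeds: dict[str, list[int]] = {}
    for i in range(len(head) - k + 1):
        seeds.setdefault(head[i : i + k], []).append(i)

    # per-diagonal high-water mark to skip seeds inside found alignments
    seen_to: dict[int, int] = {}
    candidates: list[TerminalPair] = []
    for j in range(len(target) - k + 1):
        kmer = target[j : j + k]
        for i in seeds.get(kmer, ()):  # noqa: B909
            diag = j - i
            if seen_to.get(diag, -1) >= j:
                continue
            lk, _ = _extend(head, target, i, j, -1, xdrop)
            rk, _ = _extend(head, target, i, j, +1, xdrop)
            hs, he = i - lk, i + rk
            ts, te = j - lk, j + rk
            seen_to[diag] = te
            length = he - hs
            if length < min_len:
                continue
            matches = sum(
                1 for x, y in zip(head[hs:he], target[ts:te]) if x == y
            )
            identity = matches / length
            if identity < min_identity:
                continue
            score = matches - 2 * (length - matches)
            if mode == "inverted":
                # map back from the reverse-complemented tail window
                tlen = len(target)
                t_iv = (tail_start + tlen - te, tail_start + tlen - ts)
            else:
                t_iv = (tail_start + ts, tail_start + te)
            candidates.append(
                TerminalPair(
                    head=(hs, he), tail=t_iv, identity=identity,
                    score=score, mode=mode,
                )
            )

    candidates.sort(key=lambda p: -p.score)
    kept: list[TerminalPair] = []
    for cand in candidates:
        redundant = any(
            _overlap(cand.head, p.head) > 0.5 * cand.length
            and _overlap(cand.tail, p.tail) > 0.5 * cand.length
            for p in kept
        )
        if not redundant:
            kept.append(cand)
    return kept


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def build_element_model(
    contig_id: str,
    contig_len: int,
    terminal_pairs: Sequence[TerminalPair],
    domain_hits: Sequence[tuple[int, int]],
    mode: str = "direct",
    superfamily: str = "",
) -> ElementModel:
    """Assemble an element model from terminal-repeat pairs and protein
    domain hits.

    The internal region is conservatively bounded by the first and last
    TE domains; terminals (from the best-scoring pair) are clipped to
    exclude any overlap with it.  A model whose internal region engulfs
    every terminal is rejected.
    """
    if not domain_hits:
        raise DomainError("no domain hits; internal region undefined")
    if not terminal_pairs:
        raise DomainError("no terminal repeat pair")
    internal = (min(s for s, _ in domain_hits), max(e for _, e in domain_hits))
    best = max(terminal_pairs, key=lambda p: p.score)
    terminals = []
    for s, e in (best.head, best.tail):
        # clip away any overlap with the internal region
        if s < internal[0]:
            e = min(e, internal[0])
        elif e > internal[1]:
            s = max(s, internal[1])
        else:
            continue  # fully inside internal
        if e > s:
            terminals.append((min(s, contig_len), min(e, contig_len)))
    if not terminals:
        raise StructureError(
            f"internal region {internal} engulfs all terminals on {contig_id}"
        )
    return ElementModel(
        contig_id=contig_id,
        contig_len=contig_len,
        mode=mode,
        terminals=terminals,
        internal=internal,
        superfamily=superfamily,
    )


def _region_overlap_bp(
    starts: np.ndarray, ends: np.ndarray, region: tuple[int, int]
) -> float:
    s, e = region
    return float(
        np.clip(np.minimum(ends, e) - np.maximum(starts, s), 0, None).sum()
    )


def tti_ratio(
    alignments: Sequence[ReadAlignment],
    model: ElementModel,
    min_aligned_len: int = 0,
) -> TTIResult:
    """Total-terminal-to-internal depth ratio for one contig.

    Depth over a region is the summed overlap bp of retained alignments
    divided by the region length, so a read contributes fractionally to
    a region it partially covers and a boundary-spanning read counts on
    both sides.  All terminal intervals are pooled into one "total
    terminal" class.  Alignments shorter than ``min_aligned_len`` are
    discarded first (the stringency knob of the alignment-length sweep).
    """
    if model.terminal_len <= 0 or model.internal_len <= 0:
        raise DomainError("model has empty terminal or internal regions")
    hits = [
        a
        for a in alignments
        if a.contig_id == model.contig_id and a.aligned_len >= min_aligned_len
    ]
    starts = np.array([a.start for a in hits], dtype=np.int64)
    ends = np.array([a.end for a in hits], dtype=np.int64)
    term_bp = sum(
        _region_overlap_bp(starts, ends, iv) for iv in model.terminals
    )
    int_bp = _region_overlap_bp(starts, ends, model.internal)
    depth_t = term_bp / model.terminal_len
    depth_i = int_bp / model.internal_len
    if depth_i == 0:
        raise UndefinedRatioError(
            f"no internal coverage on {model.contig_id}; TT:I undefined"
        )
    return TTIResult(
        contig_id=model.contig_id,
        depth_terminal=depth_t,
        depth_internal=depth_i,
        tti=depth_t / depth_i,
        min_aligned_len=min_aligned_len,
        n_alignments_used=len(hits),
    )


def tti_sweep(
    alignments: Sequence[ReadAlignment],
    models: Sequence[ElementModel],
    thresholds: Sequence[int] = (20, 30, 40, 50),
) -> pd.DataFrame:
    """TT:I across contigs and alignment-length stringencies.

    Returns one row per (superfamily, threshold) with the unweighted
    mean of per-contig ratios, plus per-contig values; contigs whose
    ratio is undefined at a threshold are excluded and counted.
    """
    if not thresholds:
        raise UsageError("empty threshold list")
    rows = []
    for thr in thresholds:
        per_sf: dict[str, list[TTIResult]] = {}
        undefined: dict[str, int] = {}
        for model in models:
            sf = model.superfamily or "all"
            try:
                res = tti_ratio(alignments, model, min_aligned_len=thr)
            except UndefinedRatioError:
                undefined[sf] = undefined.get(sf, 0) + 1
                continue
            per_sf.setdefault(sf, []).append(res)
        for sf in sorted(set(per_sf) | set(undefined)):
            results = per_sf.get(sf, [])
            rows.append(
                {
                    "superfamily": sf,
                    "min_aligned_len": thr,
                    "mean_tti": (
                        float(np.mean([r.tti for r in results]))
                        if results
                        else np.nan
                    ),
                    "n_contigs": len(results),
                    "n_undefined": undefined.get(sf, 0),
                    "per_contig_tti": ";".join(
                        f"{r.contig_id}={r.tti:.4f}" for r in results
                    ),
                }
            )
    return pd.DataFrame(rows)


def solo_fraction_estimate(tti: float) -> float:
    """Invert the uniform-sampling expectation TT:I = 1 + s/2 to the
    solo-per-intact-element ratio s.  Ratios below 1 (excess internal
    depth) are reported as 0."""
    if tti < 1.0:
        return 0.0
    return 2.0 * (tti - 1.0)


# ---------------------------------------------------------------------------
# tabular round-trips (BED-like element models; alignment TSV)

def write_element_models(models: Sequence[ElementModel], path_or_stream) -> None:
    rows = []
    for m in models:
        for s, e in m.terminals:
            rows.append((m.contig_id, s, e, "terminal", m.superfamily, m.mode,
                         m.contig_len))
        rows.append((m.contig_id, *m.internal, "internal", m.superfamily,
                     m.mode, m.contig_len))
    df = pd.DataFrame(
        rows,
        columns=["contig_id", "start", "end", "part", "superfamily", "mode",
                 "contig_len"],
    )
    write_tsv(df, path_or_stream)


def read_element_models(path_or_stream) -> list[ElementModel]:
    df = read_tsv(path_or_stream)
    models = []
    for contig_id, group in df.groupby("contig_id", sort=False):
        terminals = [
            (int(r.start), int(r.end))
            for r in group.itertuples()
            if r.part == "terminal"
        ]
        internals = [
            (int(r.start), int(r.end))
            for r in group.itertuples()
            if r.part == "internal"
        ]
        if len(internals) != 1:
            raise DomainError(
                f"contig {contig_id!r} needs exactly one internal interval"
            )
        first = group.iloc[0]
        models.append(
            ElementModel(
                contig_id=str(contig_id),
                contig_len=int(first["contig_len"]),
                mode=str(first["mode"]),
                terminals=terminals,
                internal=internals[0],
                superfamily=str(first["superfamily"]),
            )
        )
    return models


def write_alignments(alignments: Sequence[ReadAlignment], path_or_stream) -> None:
    df = pd.DataFrame(
        [
            (a.read_id, a.contig_id, a.start, a.end, a.aligned_len)
            for a in alignments
        ],
        columns=["read_id", "contig_id", "start", "end", "aligned_len"],
    )
    write_tsv(df, path_or_stream)


def read_alignments(path_or_stream) -> list[ReadAlignment]:
    df = read_tsv(path_or_stream)
    return [
        ReadAlignment(
            read_id=str(r.read_id), contig_id=str(r.contig_id),
            start=int(r.start), end=int(r.end),
        )
        for r in df.itertuples()
    ]
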
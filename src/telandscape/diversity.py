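"""Community-ecology diversity indices applied to genomic TE communities.

A genome's TE complement is treated as an ecological community: taxa are
TE superfamilies (or orders/classes/families) and the abundance of taxon
*i* is the proportion :math:`P_i` of surveyed sequence attributed to it.
Two standard indices summarise the community:

* Shannon index :math:`H' = -\\sum_i P_i \\ln P_i` (in nats): the
  uncertainty in the identity of a randomly drawn base/sequence.
* Gini-Simpson index :math:`D = 1 - \\sum_i P_i^2`: the probability that
  two random draws are different taxa; weights dominant taxa heavily.

Both combine richness (number of taxa) and evenness (how equally the
mass is spread).  By default, mass with an ambiguous classification
(unclassified, or resolved only to order at superfamily level) is
excluded before renormalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceTable
from .classification import is_ambiguous_taxon
from .errors import DomainError, UsageError

__all__ = [
    "TECommunity",
    "DiversityResult",
    "community_proportions",
    "shannon_index",
    "gini_simpson_index",
    "diversity_result",
    "compare_genomes",
]

_PROP_TOL = 1e-9


@dataclass(frozen=True)
class TECommunity:
    """A normalized proportion vector over TE taxa at one level."""

    level: str
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self):
        taxa = [t for t, _ in self.entries]
        if len(set(taxa)) != len(taxa):
            raise DomainError("duplicate taxa in community")
        props = np.array([p for _, p in self.entries], dtype=float)
        if len(props) == 0 or np.any(props <= 0):
            raise DomainError("community proportions must be positive")
        if abs(props.sum() - 1.0) > _PROP_TOL:
            raise DomainError(f"proportions sum to {props.sum()}, not 1")

    @property
    def proportions(self) -> np.ndarray:
        return np.array([p for _, p in self.entries], dtype=float)

    @property
    def richness(self) -> int:
        return len(self.entries)

    @classmethod
    def from_mapping(cls, mapping, level: str = "superfamily") -> "TECommunity":
        """Build a community from taxon -> non-negative mass, dropping
        zero-mass taxa and renormalizing."""
        items = [(str(t), float(m)) for t, m in dict(mapping).items() if m > 0]
        total = sum(m for _, m in items)
        if total <= 0:
            raise DomainError("no positive mass to build a community from")
        return cls(level=level, entries=tuple((t, m / total) for t, m in items))


@dataclass(frozen=True)
class DiversityResult:
    shannon: float
    gini_simpson: float
    richness: int


def community_proportions(
    table: AbundanceTable, include_unclassified: bool = False
) -> TECommunity:
    """Turn an abundance table into a proportion vector.

    With ``include_unclassified=False`` (default) ambiguously classified
    mass is dropped before renormalizing to sum 1; with ``True`` the
    ambiguous rows are retained as taxa of their own.
    """
    df = table.table
    if not include_unclassified:
        df = df[~df["taxon"].map(is_ambiguous_taxon)]
    mapping = dict(zip(df["taxon"], df["masked_bp"]))
    try:
        return TECommunity.from_mapping(mapping, level=table.level)
    except DomainError:
        raise DomainError(
            "no classified mass retained at level "
            f"{table.level!r}; nothing to normalize"
        )


def shannon_index(c: TECommunity) -> float:
    """Shannon index H' = -sum(p ln p), in nats.  0 for one taxon."""
    p = c.proportions
    return float(-(p * np.log(p)).sum())


def gini_simpson_index(c: TECommunity) -> float:
    """Gini-Simpson index D = 1 - sum(p^2): probability two random draws
    are different taxa."""
    p = c.proportions
    return float(1.0 - (p * p).sum())


def diversity_result(c: TECommunity) -> DiversityResult:
    res = DiversityResult(
        shannon=shannon_index(c),
        gini_simpson=gini_simpson_index(c),
        richness=c.richness,
    )
    # bounds implied by the index definitions
    assert -1e-12 <= res.shannon <= math.log(res.richness) + 1e-12
    assert -1e-12 <= res.gini_simpson <= 1.0 - 1.0 / res.richness + 1e-12
    return res


def compare_genomes(
    communities: list[tuple[str, float, TECommunity]],
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Cross-genome diversity comparison.

    ``communities`` is a list of (name, genome_size_gb, community).
    Returns one row per genome (name, genome size, Shannon,
    Gini-Simpson, richness) plus the Spearman rank correlation (rho,
    two-sided p) of genome size against each index — the test of whether
    larger genomes carry less diverse TE communities.
    """
    if len(communities) < 2:
        raise UsageError("need at least two genomes to compare")
    names = [n for n, _, _ in communities]
    if len(set(names)) != len(names):
        raise UsageError("duplicate genome names")

    rows = []
    for name, size_gb, comm in communities:
        res = diversity_result(comm)
        rows.append(
            {
                "name": name,
                "genome_size_gb": size_gb,
                "shannon": res.shannon,
                "gini_simpson": res.gini_simpson,
                "richness": res.richness,
            }
        )
    df = pd.DataFrame(rows)
    correlations = {}
    for index_col in ("shannon", "gini_simpson"):
        rho, p = stats.spearmanr(df["genome_size_gb"], df[index_col])
        correlations[index_col] = (float(rho), float(p))
    return df, correlations
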
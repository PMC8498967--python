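"""Divergence landscapes and amplification-history calling.

Each sequenced read that masks to a TE superfamily carries the percent
divergence from its closest (least divergent) consensus.  Binning those
divergences (1% bins by default) per superfamily yields a *divergence
landscape* whose shape records the superfamily's amplification history:
young, expanding superfamilies pile mass near 0% divergence, past
bursts leave an interior mode, and extinct superfamilies show a mode at
high divergence with nothing recent.

A superfamily is called *active* when (a) more than a small fraction of
its mass lies below 1% divergence and (b) the landscape shape is one
consistent with ongoing accumulation (monotonically decreasing,
unimodal right-skewed, J-shaped, or bimodal with a recent mode).  The
paper-of-record style shape taxonomy is reproduced here as a
deterministic decision procedure over a lightly smoothed histogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .abundance import AbundanceTable
from .errors import DomainError, UsageError
from .repeatio import RepeatRecord

__all__ = [
    "DivergenceLandscape",
    "ActivityCall",
    "best_hit_divergence",
    "build_landscape",
    "classify_activity",
    "activity_summary",
    "ACTIVE_SHAPES",
    "INACTIVE_SHAPES",
]

ACTIVE_SHAPES = frozenset(
    {
        "monotonic_decreasing",
        "unimodal_right_skewed",
        "unimodal_right_skewed_recent_spike",
        "j_shaped_left",
        "bimodal_recent",
    }
)
INACTIVE_SHAPES = frozenset({"unimodal_inactive", "other_inactive"})


@dataclass
class DivergenceLandscape:
    """Histogram of read-to-consensus divergence for one superfamily.

    ``bins[k]`` holds the mass (read count or masked bp) with divergence
    in the half-open interval [k*bin_width, (k+1)*bin_width).
    """

    superfamily: str
    bins: np.ndarray
    bin_width: float = 1.0
    weight: str = "reads"

    def __post_init__(self):
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bin_width <= 0:
            raise UsageError("bin_width must be positive")
        if np.any(self.bins < 0):
            raise DomainError("negative bin mass")

    @property
    def total_mass(self) -> float:
        return float(self.bins.sum())

    def recent_fraction(self, window_pct: float = 1.0) -> float:
        """Fraction of raw mass at divergence below ``window_pct``."""
        if self.total_mass == 0:
            raise DomainError("empty landscape")
        n_full = int(window_pct // self.bin_width)
        mass = self.bins[:n_full].sum()
        # partial bin when the window is not a multiple of the bin width
        rem = window_pct - n_full * self.bin_width
        if rem > 0 and n_full < len(self.bins):
            mass += self.bins[n_full] * (rem / self.bin_width)
        return float(mass / self.total_mass)


@dataclass(frozen=True)
class ActivityCall:
    superfamily: str
    shape: str
    active: bool
    recent_fraction: float


def best_hit_divergence(
    records: Sequence[RepeatRecord],
) -> pd.DataFrame:
    """Reduce per-hit records to one row per query: the least divergent
    hit, with ties broken by higher score then input order.

    Returns columns ``query_id``, ``superfamily``, ``pct_div``,
    ``masked_bp`` (the best hit's span, used for bp weighting).  Queries
    whose only hits are unclassified are emitted with the
    ``unclassified`` label rather than dropped.
    """
    best: dict[str, tuple[tuple[float, float, int], RepeatRecord]] = {}
    for i, rec in enumerate(records):
        key = (rec.pct_div, -rec.score, i)
        prev = best.get(rec.query_id)
        if prev is None or key < prev[0]:
            best[rec.query_id] = (key, rec)
    rows = [
        {
            "query_id": qid,
            "superfamily": rec.classification.render_level("superfamily"),
            "pct_div": rec.pct_div,
            "masked_bp": rec.span,
        }
        for qid, (_, rec) in best.items()
    ]
    return pd.DataFrame(
        rows, columns=["query_id", "superfamily", "pct_div", "masked_bp"]
    )


def build_landscape(
    divs: pd.DataFrame,
    weight: str = "reads",
    bin_width: float = 1.0,
) -> list[DivergenceLandscape]:
    """Bin best-hit divergences into per-superfamily landscapes.

    ``weight='reads'`` counts queries; ``weight='bp'`` sums the masked bp
    of each best hit.  Bins are half-open [k*w, (k+1)*w).
    """
    if bin_width <= 0:
        raise UsageError("bin_width must be positive")
    if weight not in ("reads", "bp"):
        raise UsageError(f"weight must be 'reads' or 'bp', got {weight!r}")
    out = []
    for superfamily, group in divs.groupby("superfamily", sort=True):
        d = group["pct_div"].to_numpy(dtype=float)
        w = group["masked_bp"].to_numpy(dtype=float) if weight == "bp" else None
        n_bins = int(np.floor(d.max() / bin_width)) + 1
        edges = np.arange(n_bins + 1) * bin_width
        # np.histogram closes the last bin; widen it to keep [k*w,(k+1)*w)
        edges[-1] = np.nextafter(edges[-1], np.inf)
        counts, _ = np.histogram(d, bins=edges, weights=w)
        out.append(
            DivergenceLandscape(
                superfamily=str(superfamily),
                bins=counts,
                bin_width=bin_width,
                weight=weight,
            )
        )
    return out


def _smooth(profile: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window truncates at the edges."""
    if window <= 1:
        return profile.astype(float)
    half = window // 2
    out = np.empty_like(profile, dtype=float)
    for i in range(len(profile)):
        lo, hi = max(0, i - half), min(len(profile), i + half + 1)
        out[i] = profile[lo:hi].mean()
    return out


def classify_activity(
    landscape: DivergenceLandscape,
    smooth_window: int = 3,
    recent_threshold: float = 0.005,
    mono_tol: float = 0.05,
    mode_prominence: float = 0.10,
) -> ActivityCall:
    """Call the amplification-history shape and activity of a landscape.

    Procedure: normalize the bins; smooth with a centered moving average
    (width ``smooth_window``); measure the raw mass below 1% divergence
    (``recent_fraction``); locate modes as local maxima of the smoothed
    profile exceeding ``mode_prominence`` of its global maximum; then
    apply the shape rules in order (monotonically decreasing; unimodal
    right-skewed, optionally with a recent spike; J-shaped; bimodal with
    a recent mode).  A landscape whose recent fraction does not exceed
    ``recent_threshold`` is inactive regardless of shape.
    """
    if landscape.total_mass <= 0:
        raise DomainError("cannot classify an empty landscape")
    raw = landscape.bins / landscape.total_mass
    smoothed = _smooth(raw, smooth_window)
    recent = landscape.recent_fraction(1.0)

    # modes: local maxima (edges eligible) above the prominence floor
    padded = np.concatenate(([-np.inf], smoothed, [-np.inf]))
    peaks, _ = find_peaks(padded, height=mode_prominence * smoothed.max())
    modes = [int(p - 1) for p in peaks]
    n_modes = len(modes)

    shape = "other_inactive"
    if (
        np.all(smoothed[1:] <= smoothed[:-1] * (1.0 + mono_tol))
        and modes
        and modes[0] == 0
    ):
        shape = "monotonic_decreasing"
    elif n_modes == 1:
        mode = modes[0]
        occupied = np.nonzero(raw)[0]
        top_decile_start = occupied[0] + 0.9 * (occupied[-1] - occupied[0])
        left = raw[:mode].sum()
        right = raw[mode + 1:].sum()
        if mode >= top_decile_start and left > right:
            shape = "j_shaped_left"
        elif right + raw[mode] > left:
            spike = raw[0] > 2.0 * smoothed[0]
            shape = (
                "unimodal_right_skewed_recent_spike"
                if spike
                else "unimodal_right_skewed"
            )
    elif n_modes >= 2 and any(m <= 1 for m in modes):
        shape = "bimodal_recent"

    if recent <= recent_threshold:
        shape = "unimodal_inactive" if n_modes == 1 else "other_inactive"
        active = False
    else:
        active = shape in ACTIVE_SHAPES
        if not active:
            shape = "other_inactive"
    return ActivityCall(
        superfamily=landscape.superfamily,
        shape=shape,
        active=active,
        recent_fraction=recent,
    )


def activity_summary(
    landscapes: Sequence[DivergenceLandscape],
    abundance: AbundanceTable | None = None,
    min_genome_fraction: float = 0.00005,
    **classify_kwargs,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every sufficiently abundant superfamily.

    Superfamilies below ``min_genome_fraction`` of the genome (default
    0.005%) are excluded from assessment — rare superfamilies yield too
    few masked reads for a stable histogram.  When no abundance table is
    supplied, every landscape is assessed.

    Returns a per-superfamily table of calls plus
    ``{"n_assessed": ..., "n_active": ...}``.
    """
    rows = []
    n_active = 0
    n_assessed = 0
    for ls in landscapes:
        if abundance is not None:
            frac = abundance.pct_of(ls.superfamily) / 100.0
            if frac < min_genome_fraction:
                continue
        call = classify_activity(ls, **classify_kwargs)
        n_assessed += 1
        n_active += int(call.active)
        rows.append(
            {
                "superfamily": call.superfamily,
                "shape": call.shape,
                "active": call.active,
                "recent_fraction": call.recent_fraction,
                "total_mass": ls.total_mass,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["superfamily", "shape", "active", "recent_fraction", "total_mass"],
    )
    return df, {"n_assessed": n_assessed, "n_active": n_active}


def landscape_table(landscapes: Sequence[DivergenceLandscape]) -> pd.DataFrame:
    """Long-form TSV-ready table (superfamily, bin_start, mass)."""
    rows = []
    for ls in landscapes:
        for k, mass in enumerate(ls.bins):
            if mass > 0:
                rows.append(
                    {
                        "superfamily": ls.superfamily,
                        "bin_start": k * ls.bin_width,
                        "mass": mass,
                    }
                )
    return pd.DataFrame(rows, columns=["superfamily", "bin_start", "mass"])
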
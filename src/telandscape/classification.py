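"""Hierarchical TE classification labels.

Transposable elements are organised hierarchically: class (I =
retrotransposons, II = DNA transposons), order (e.g. LTR, LINE, TIR),
and superfamily (e.g. Gypsy, Jockey, hAT).  Families sit below the
superfamily and are delimited operationally at 80% sequence identity
(see :mod:`telandscape.famcluster`).  Non-autonomous derivatives that
lack coding capacity — SINEs, MITEs, TRIMs, LARDs — carry an explicit
tag because several analyses treat them separately.

Annotation tools render these labels in several dialects
(``ClassI/LTR/Gypsy``, ``LTR/Gypsy``, ``DNA/hAT``, bare ``LINE``,
``Unknown``).  :func:`parse_classification_label` normalizes all of them
through an editable alias table shipped as package data; anything it
cannot interpret degrades to *unclassified* and is logged, never raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

log = logging.getLogger(__name__)

TE_CLASSES = ("I", "II", "unclassified")
NONAUTONOMOUS_KINDS = ("TRIM", "LARD", "MITE", "SINE", "none")

#: standalone tags for non-autonomous element groups: tag -> (class, order)
_NONAUT_TAGS = {
    "TRIM": ("I", "LTR"),
    "LARD": ("I", "LTR"),
    "MITE": ("II", "TIR"),
}

_UNKNOWN_TOKENS = {"", "unknown", "unclassified", "unspecified", "none", "?"}


@lru_cache(maxsize=4)
def load_classification_map(path: str | None = None) -> dict:
    """Load the classification dialect table (YAML).

    With no argument the table shipped with the package is used; pass a
    path to substitute a site-specific table with the same keys
    (``orders``, ``order_aliases``, ``superfamily_aliases``,
    ``superfamilies``).
    """
    if path is None:
        text = (
            resources.files("telandscape") / "data/classification_map.yaml"
        ).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    order_to_class = {}
    for cls, orders in raw["orders"].items():
        for o in orders:
            order_to_class[o.upper()] = (str(cls), o)
    sf_canon = {}
    for order, sfs in raw.get("superfamilies", {}).items():
        for sf in sfs:
            sf_canon[str(sf).upper()] = str(sf)
    return {
        "order_to_class": order_to_class,
        "order_aliases": {
            k.upper(): v for k, v in raw.get("order_aliases", {}).items()
        },
        "superfamily_aliases": {
            k.upper(): str(v) for k, v in raw.get("superfamily_aliases", {}).items()
        },
        "superfamily_canon": sf_canon,
    }


@dataclass(frozen=True)
class ClassificationLabel:
    """A TE classification at the deepest level known.

    Invariants: a superfamily implies an order; *unclassified* implies
    neither order nor superfamily.
    """

    te_class: str = "unclassified"
    order: str | None = None
    superfamily: str | None = None
    nonautonomous_kind: str = "none"

    def __post_init__(self):
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"bad te_class {self.te_class!r}")
        if self.nonautonomous_kind not in NONAUTONOMOUS_KINDS:
            raise ValueError(f"bad nonautonomous_kind {self.nonautonomous_kind!r}")
        if self.superfamily is not None and self.order is None:
            raise ValueError("superfamily requires an order")
        if self.te_class == "unclassified" and (
            self.order is not None or self.superfamily is not None
        ):
            raise ValueError("unclassified label cannot carry order/superfamily")

    @property
    def is_classified(self) -> bool:
        return self.te_class != "unclassified"

    def render(self) -> str:
        """Canonical text form; ``parse_classification_label`` round-trips it."""
        if not self.is_classified:
            return "Unknown"
        if self.nonautonomous_kind in _NONAUT_TAGS and self.superfamily is None:
            return self.nonautonomous_kind
        parts = [f"Class{self.te_class}"]
        if self.order:
            parts.append(self.order)
        if self.superfamily:
            parts.append(self.superfamily)
        return "/".join(parts)

    def render_level(self, level: str) -> str:
        """Taxon name at a chosen rollup level (class/order/superfamily).

        Mass not resolved at the requested level is labelled
        ``unclassified`` (wholly unknown) or ``<order>/unclassified``
        (order-only at superfamily level) so downstream stages can filter
        ambiguous classifications.
        """
        if level == "class":
            return f"Class{self.te_class}" if self.is_classified else "unclassified"
        if level == "order":
            if not self.is_classified:
                return "unclassified"
            if self.nonautonomous_kind in _NONAUT_TAGS and self.superfamily is None:
                return self.nonautonomous_kind
            return self.order or "unclassified"
        if level == "superfamily":
            if not self.is_classified:
                return "unclassified"
            if self.nonautonomous_kind in _NONAUT_TAGS and self.superfamily is None:
                return self.nonautonomous_kind
            if self.superfamily is None:
                return f"{self.order}/unclassified"
            return f"{self.order}/{self.superfamily}"
        raise ValueError(f"unknown level {level!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


UNCLASSIFIED = ClassificationLabel()


def is_ambiguous_taxon(taxon: str) -> bool:
    """True for taxon names that are not resolved to the full depth of a
    rollup level (used when excluding ambiguous mass from communities)."""
    return taxon == "unclassified" or taxon.endswith("/unclassified")


def parse_classification_label(
    label: str, config_path: str | None = None
) -> ClassificationLabel:
    """Parse a classification label in any supported dialect.

    Accepts Wicker-style paths (``ClassI/LTR/Gypsy``), masker-style
    suffixes (``LTR/Gypsy``, ``DNA/hAT``), order-only labels (``LINE``),
    non-autonomous tags (``MITE``, ``TRIM``, ``LARD``), and ``Unknown``.
    Unparseable text degrades to unclassified (logged at DEBUG).
    """
    cfg = load_classification_map(config_path)
    text = (label or "").strip().strip("/")
    if text.lower() in _UNKNOWN_TOKENS:
        return UNCLASSIFIED

    tokens = [t for t in text.replace("\\", "/").split("/") if t]
    # optional explicit class prefix
    te_class = None
    if tokens and tokens[0].upper().replace(" ", "") in ("CLASSI", "CLASS1"):
        te_class, tokens = "I", tokens[1:]
    elif tokens and tokens[0].upper().replace(" ", "") in ("CLASSII", "CLASS2"):
        te_class, tokens = "II", tokens[1:]
    if not tokens:
        if te_class is not None:  # "ClassI" alone: class-level only
            return ClassificationLabel(te_class=te_class)
        return UNCLASSIFIED

    head = tokens[0].upper()
    # standalone non-autonomous tags
    if head in _NONAUT_TAGS and len(tokens) == 1:
        cls, order = _NONAUT_TAGS[head]
        return ClassificationLabel(
            te_class=cls, order=order, nonautonomous_kind=head
        )

    head = cfg["order_aliases"].get(head, tokens[0])
    entry = cfg["order_to_class"].get(head.upper())
    if entry is None:
        log.debug("unrecognized classification label %r -> unclassified", label)
        return UNCLASSIFIED
    cls_from_order, order = entry
    te_class = te_class or cls_from_order

    superfamily = None
    if len(tokens) > 1 and tokens[1].lower() not in _UNKNOWN_TOKENS:
        raw_sf = tokens[1]
        key = raw_sf.upper()
        superfamily = cfg["superfamily_aliases"].get(
            key, cfg["superfamily_canon"].get(key, raw_sf)
        )

    kind = "SINE" if order == "SINE" else "none"
    return ClassificationLabel(
        te_class=te_class,
        order=order,
        superfamily=superfamily,
        nonautonomous_kind=kind,
    )
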
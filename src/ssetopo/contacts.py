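"""Significant long-range contact screening and mapping to segment pairs.

Predicted residue contact lists contain thousands of pairs of very mixed
reliability.  Only the most significant long-range pairs are informative
about tertiary packing, so the screen proceeds in three steps:

1. remove pairs with near-zero confidence;
2. remove short-range pairs (few residues separating the partners);
3. keep pairs whose confidence exceeds the mean by k standard deviations,
   cascading k = 3 → 2 → 1 until at least two distinct secondary-structure
   contact pairs emerge.

Selected residue pairs are then aggregated to segment pairs: a contact
(i, j) supports (Sa, Sb) when i lies within Sa and j within Sb, Sa ≠ Sb.
Contacts touching a loop or turn are counted but carry no segment-level
information; in practice most significant pairs fall in this bucket.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .model import ContactPair, SSContactPair, ScreeningConfig, SegmentSet

__all__ = [
    "ContactMapping",
    "ScreeningResult",
    "filter_long_range",
    "map_contacts",
    "map_to_segment_pairs",
    "select_significant",
]


def filter_long_range(
    contacts: Sequence[ContactPair], cfg: ScreeningConfig = ScreeningConfig()
) -> List[ContactPair]:
    """Drop near-zero-confidence and short-range pairs.

    A pair is short-range when the number of residues strictly between the
    partners is <= ``cfg.min_separation`` (default 3, i.e. drop j − i ≤ 4).
    """
    return [
        c
        for c in contacts
        if c.p >= cfg.near_zero_eps and c.separation > cfg.min_separation
    ]


@dataclass(frozen=True)
class ContactMapping:
    """Aggregation of residue contacts to segment pairs, with accounting.

    ``ss_pairs`` holds the distinct segment pairs with their supporting
    contact counts; ``unmapped`` counts contacts with at least one residue
    outside every segment; ``same_segment`` counts contacts internal to a
    single segment.  The three buckets partition the input.
    """

    ss_pairs: Tuple[SSContactPair, ...]
    unmapped: int
    same_segment: int

    @property
    def n_mapped(self) -> int:
        return sum(p.n_pairs for p in self.ss_pairs)


def map_contacts(
    contacts: Sequence[ContactPair], segs: SegmentSet
) -> ContactMapping:
    """Map residue contacts onto pairs of secondary-structure segments."""
    counts: dict = {}
    unmapped = 0
    same_segment = 0
    for c in contacts:
        seg_i = segs.segment_of_residue(c.i)
        seg_j = segs.segment_of_residue(c.j)
        if seg_i is None or seg_j is None:
            unmapped += 1
            continue
        if seg_i.id == seg_j.id:
            same_segment += 1
            continue
        a, b = sorted((seg_i.id, seg_j.id), key=lambda s: segs.index_of(s))
        counts[(a, b)] = counts.get((a, b), 0) + 1
    pairs = tuple(
        SSContactPair(a, b, n)
        for (a, b), n in sorted(
            counts.items(),
            key=lambda kv: (segs.index_of(kv[0][0]), segs.index_of(kv[0][1])),
        )
    )
    return ContactMapping(pairs, unmapped, same_segment)


def map_to_segment_pairs(
    contacts: Sequence[ContactPair], segs: SegmentSet
) -> List[SSContactPair]:
    """The distinct segment pairs supported by the given contacts."""
    return list(map_contacts(contacts, segs).ss_pairs)


@dataclass(frozen=True)
class ScreeningResult:
    selected: Tuple[ContactPair, ...]
    sd_level: Optional[float]
    ss_pairs: Tuple[SSContactPair, ...]
    mapping: Optional[ContactMapping] = None


def select_significant(
    contacts: Sequence[ContactPair],
    segs: SegmentSet,
    cfg: ScreeningConfig = ScreeningConfig(),
) -> ScreeningResult:
    """Select significant long-range contacts by the binned SD cascade.

    The mean μ and sample standard deviation σ are computed over the
    long-range-filtered confidences.  At each level k in ``cfg.sd_levels``
    the pairs with p > μ + k·σ are kept and mapped to segment pairs; the
    cascade stops at the first level yielding at least
    ``cfg.min_ss_pairs_to_stop`` distinct segment pairs.  If even the last
    level falls short, its result is returned as-is with a warning.
    """
    contacts = list(contacts)
    if not contacts:
        warnings.warn("empty contact list; nothing to screen")
        return ScreeningResult((), None, ())
    ps = [c.p for c in contacts]
    mu = statistics.fmean(ps)
    sigma = statistics.stdev(ps) if len(ps) > 1 else 0.0

    result = ScreeningResult((), cfg.sd_levels[-1], ())
    for level in cfg.sd_levels:
        threshold = mu + level * sigma
        selected = tuple(c for c in contacts if c.p > threshold)
        mapping = map_contacts(selected, segs)
        result = ScreeningResult(selected, level, mapping.ss_pairs, mapping)
        if len(mapping.ss_pairs) >= cfg.min_ss_pairs_to_stop:
            return result
    warnings.warn(
        f"contact screen found only {len(result.ss_pairs)} segment pair(s) "
        f"even at {cfg.sd_levels[-1]}SD; returning that selection"
    )
    return result
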
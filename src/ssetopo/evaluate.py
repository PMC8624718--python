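"""Evaluation against a ground-truth segment↔trace correspondence.

A candidate match (S, L, direction) is correct when the truth maps S to L
with the same direction.  Matches involving segments or traces that are not
correctly predicted secondary structures never count, even if they happen to
pair up plausibly.  The maximum-match topology is the candidate achieving
the largest number of correct matches; its best (smallest) rank and that
count summarize a ranking's quality.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

from .model import GroundTruth, RankedTopology, Topology

__all__ = ["count_correct_matches", "max_match_rank"]


def count_correct_matches(t: Topology, truth: GroundTruth) -> int:
    """Number of matches in ``t`` agreeing with the truth correspondence.

    A truth pair whose direction is ``None`` (written ``*`` in truth files)
    is direction-agnostic: either alignment of the correct trace counts.
    This accommodates traces of one helical turn whose orientation is not
    meaningful; by default truth files state explicit directions and the
    strict metric applies.
    """
    n = 0
    for m in t.matches:
        if m.segment not in truth.correct_segments:
            continue
        if m.trace not in truth.correct_traces:
            continue
        entry = truth.pairs.get(m.segment)
        if entry is None:
            continue
        true_trace, true_dir = entry
        if m.trace != true_trace:
            continue
        if true_dir is None or m.direction is true_dir:
            n += 1
    return n


def max_match_rank(
    ranked: Sequence[RankedTopology], truth: GroundTruth
) -> Tuple[Optional[int], int]:
    """Best rank of the maximum-match topology, and its correct-pair count.

    Ranks follow the list order (1-based).  Returns ``(None, 0)`` when no
    candidate matches any truth pair — the case reported as NA when a
    ranking misses the correct topology entirely.
    """
    best_rank: Optional[int] = None
    best_count = 0
    for pos, rt in enumerate(ranked, start=1):
        c = count_correct_matches(rt.topology, truth)
        if c > best_count:
            best_count = c
            best_rank = pos
    if best_count == 0:
        return None, 0
    return best_rank, best_count
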
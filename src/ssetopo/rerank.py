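"""Re-ranking of initial topologies by contact satisfaction.

When two residues are predicted to be in contact, the secondary structures
holding them must be close in space.  Each initial topology assigns
contact-supported segment pairs to concrete trace pairs, whose shortest
line-to-line distance can be checked against a contact threshold:

* CP — the number of contact-supported segment pairs whose two segments are
  both assigned a trace in the topology;
* SP — the subset of those whose traces lie within the threshold
  (default 13 Å: roughly two helix radii of ~5 Å plus contact reach).

Topologies are sorted by the ratio SP/CP (descending), giving each a
``rank_update``; the final ordering fuses the geometric and contact ranks as

    score = a · rank_init + (1 − a) · rank_update,      a = 0.7

so that neither information source dominates and an error in either is
damped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .geometry import segment_distance
from .model import (
    InputError,
    RankedTopology,
    SSContactPair,
    Topology,
    TraceSet,
)

__all__ = ["RerankConfig", "contact_satisfaction", "rerank"]


@dataclass(frozen=True)
class RerankConfig:
    """Contact distance threshold (Å) and rank-fusion weight a ∈ [0, 1]."""

    contact_distance_max: float = 13.0
    weight_a: float = 0.7

    def __post_init__(self) -> None:
        if self.contact_distance_max <= 0:
            raise InputError("contact_distance_max must be positive")
        if not (0.0 <= self.weight_a <= 1.0):
            raise InputError("weight_a must lie in [0, 1]")


def contact_satisfaction(
    t: Topology,
    ss_contacts: Sequence[SSContactPair],
    traces: TraceSet,
    cfg: RerankConfig = RerankConfig(),
    *,
    _distance_cache: Dict[Tuple[str, str], float] = None,
) -> Tuple[int, int]:
    """Count contact-supported pairs (CP) and satisfied pairs (SP).

    Only segment pairs with BOTH segments matched in the topology count
    toward CP — an unmatched segment has no trace to measure.  A pair is
    satisfied when the shortest distance between the two assigned traces is
    strictly below the threshold.
    """
    cache = _distance_cache if _distance_cache is not None else {}
    cp = 0
    sp = 0
    for pair in ss_contacts:
        a = t.trace_of(pair.seg_a)
        b = t.trace_of(pair.seg_b)
        if a is None or b is None:
            continue
        cp += 1
        key = tuple(sorted((a[0], b[0])))
        if key not in cache:
            cache[key] = segment_distance(traces.by_id(key[0]), traces.by_id(key[1]))
        if cache[key] < cfg.contact_distance_max:
            sp += 1
    return cp, sp


def rerank(
    ranked: Sequence[RankedTopology],
    ss_contacts: Sequence[SSContactPair],
    traces: TraceSet,
    cfg: RerankConfig = RerankConfig(),
) -> List[RankedTopology]:
    """Fuse the initial geometric ranking with contact satisfaction.

    Fills ``cp``, ``sp``, ``rank_update`` and ``fused_score`` on every input
    topology and returns the list re-sorted by fused score (ascending), ties
    broken by ``rank_init``.  Topologies with CP = 0 take ratio 0 and hence
    sort below any topology satisfying at least one contact at the ratio
    stage.  The input list is not modified.
    """
    if not ranked:
        return []
    cache: Dict[Tuple[str, str], float] = {}
    out = []
    for rt in ranked:
        cp, sp = contact_satisfaction(
            rt.topology, ss_contacts, traces, cfg, _distance_cache=cache
        )
        out.append(
            RankedTopology(rt.topology, rt.dp_score, rt.rank_init, cp=cp, sp=sp)
        )
    # rank by ratio descending, ties by initial rank (ordinal ranking)
    by_ratio = sorted(out, key=lambda rt: (-rt.contact_ratio, rt.rank_init))
    for pos, rt in enumerate(by_ratio, start=1):
        rt.rank_update = pos
        rt.fused_score = cfg.weight_a * rt.rank_init + (1.0 - cfg.weight_a) * pos
    out.sort(key=lambda rt: (rt.fused_score, rt.rank_init))
    return out
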
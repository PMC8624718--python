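"""Generation and initial ranking of candidate topologies.

A topology assigns predicted sequence segments to detected traces, like type
to like type (helix segments to α-traces, strand segments to β-traces), in
N→C sequence order, with a direction per trace.  With M segments and N
traces of one type, the candidate space has C(max(M,N), min(M,N)) · min(M,N)!
· 2^min(M,N) members; mixed α/β proteins multiply the per-type spaces.

The geometric score of a topology measures the agreement between loop
lengths predicted from the sequence and the observed distances between
consecutive traces (measured along the density-map skeleton when one is
available, else in a straight line).  Loops can be compact but cannot exceed
the stretched backbone, so each consecutive pair contributes a one-sided
hinge penalty: ``max(0, observed_gap − rise·loop_residues − slack)``.  Lower
scores are better.

Two rankers are provided: :func:`enumerate_bruteforce` scores every
candidate (the exact reference, guarded against combinatorial blow-up), and
:func:`rank_topologies_dp` runs a best-first search over the layered
assignment graph that returns the top-k list identical, score for score, to
the brute-force ranking.
"""

from __future__ import annotations

import heapq
import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import SkeletonGraph
from .model import (
    Direction,
    InputError,
    Match,
    RankedTopology,
    SSEType,
    SegmentSet,
    Skeleton,
    Topology,
    TraceSet,
)

__all__ = [
    "DPConfig",
    "count_topologies",
    "TraceDistanceTable",
    "topology_score",
    "enumerate_bruteforce",
    "rank_topologies_dp",
]

_DIRS = (Direction.FORWARD, Direction.REVERSE)


@dataclass(frozen=True)
class DPConfig:
    """Tunable parameters of initial topology generation.

    rise_per_residue
        Upper bound on the backbone span of one loop residue (Å); 3.8 Å is
        the Cα-Cα virtual bond length, i.e. a fully stretched loop.
    loop_slack
        Additive slack (Å) absorbing trace-endpoint error before a gap is
        penalized.
    skip_penalty
        Å-equivalent cost per predicted segment left unmatched (applies when
        more segments are predicted than traces detected).
    distance_mode
        "skeleton" routes inter-trace gaps along the density skeleton,
        "euclidean" uses straight-line distance, "auto" picks skeleton
        whenever one is supplied.
    """

    k_top: int = 5000
    rise_per_residue: float = 3.8
    loop_slack: float = 5.0
    skip_penalty: float = 10.0
    distance_mode: str = "auto"

    def __post_init__(self) -> None:
        if self.k_top < 1:
            raise InputError("k_top must be >= 1")
        if min(self.rise_per_residue, self.loop_slack) < 0 or self.skip_penalty < 0:
            raise InputError("lengths and penalties must be non-negative")
        if self.distance_mode not in ("auto", "skeleton", "euclidean"):
            raise InputError(f"unknown distance_mode {self.distance_mode!r}")


def count_topologies(m: int, n: int) -> int:
    """Number of candidate topologies for m segments and n traces (one type).

    C(max(m,n), min(m,n)) · min(m,n)! · 2^min(m,n): the larger side
    contributes the subset choice, the smaller side is fully used, each
    matched trace can take either direction.  Symmetric in (m, n), which
    generalizes the classical M ≥ N counting to the M < N regime.
    """
    if m < 0 or n < 0:
        raise InputError("m and n must be non-negative")
    k = min(m, n)
    return math.comb(max(m, n), k) * math.factorial(k) * (1 << k)


class TraceDistanceTable:
    """Precomputed distances between all directed trace endpoints.

    Entry (exit endpoint of trace a under its direction, entry endpoint of
    trace b under its direction) is the observed gap a loop must span.  The
    same table backs both the brute-force and the DP ranker so that their
    scores are bit-identical.
    """

    def __init__(
        self,
        traces: TraceSet,
        skeleton: Optional[Skeleton] = None,
        distance_mode: str = "auto",
    ):
        self.traces = traces
        self._index = {t.id: k for k, t in enumerate(traces)}
        points = np.empty((2 * len(traces), 3))
        for k, t in enumerate(traces):
            points[2 * k] = t.p_start
            points[2 * k + 1] = t.p_end
        use_skeleton = distance_mode == "skeleton" or (
            distance_mode == "auto" and skeleton is not None
        )
        if use_skeleton:
            if skeleton is None:
                raise InputError("distance_mode='skeleton' requires a skeleton")
            self.matrix = SkeletonGraph(skeleton).distance_matrix(points)
        else:
            diff = points[:, None, :] - points[None, :, :]
            self.matrix = np.linalg.norm(diff, axis=-1)

    def gap(
        self,
        trace_a: str,
        dir_a: Direction,
        trace_b: str,
        dir_b: Direction,
    ) -> float:
        """Distance from the C-side exit of trace_a to the N-side entry of trace_b."""
        ka, kb = self._index[trace_a], self._index[trace_b]
        exit_idx = 2 * ka + (1 if dir_a is Direction.FORWARD else 0)
        entry_idx = 2 * kb + (0 if dir_b is Direction.FORWARD else 1)
        return float(self.matrix[exit_idx, entry_idx])


def _n_unmatched(segs: SegmentSet, traces: TraceSet) -> int:
    return sum(
        max(0, len(segs.of_type(t)) - len(traces.of_type(t)))
        for t in (SSEType.HELIX, SSEType.STRAND)
    )


def _pair_term(
    gap: float, loop_residues: int, cfg: DPConfig
) -> float:
    expected = cfg.rise_per_residue * loop_residues
    return max(0.0, gap - expected - cfg.loop_slack)


def topology_score(
    t: Topology,
    segs: SegmentSet,
    traces: TraceSet,
    skeleton: Optional[Skeleton] = None,
    cfg: DPConfig = DPConfig(),
    *,
    distances: Optional[TraceDistanceTable] = None,
) -> float:
    """Å-mismatch score of one topology (lower is better).

    Sum over consecutive matched pairs of the hinge loop penalty, plus
    ``skip_penalty`` per predicted segment left unmatched.  Residues of a
    skipped segment count toward the loop spanning it.
    """
    t.validate(segs, traces)
    if distances is None:
        distances = TraceDistanceTable(traces, skeleton, cfg.distance_mode)
    score = 0.0
    for prev, curr in zip(t.matches, t.matches[1:]):
        seg_a = segs.by_id(prev.segment)
        seg_b = segs.by_id(curr.segment)
        loop = segs.loop_residues_between(seg_a, seg_b)
        gap = distances.gap(prev.trace, prev.direction, curr.trace, curr.direction)
        score += _pair_term(gap, loop, cfg)
    score += cfg.skip_penalty * _n_unmatched(segs, traces)
    return score


def _required_per_type(segs: SegmentSet, traces: TraceSet) -> Dict[SSEType, int]:
    return {
        t: min(len(segs.of_type(t)), len(traces.of_type(t)))
        for t in (SSEType.HELIX, SSEType.STRAND)
    }


def _per_type_assignments(
    segs: SegmentSet, traces: TraceSet, sse_type: SSEType
) -> List[Tuple[Tuple[str, str, Direction], ...]]:
    """All (segment, trace, direction) assignments for one SSE type."""
    type_segs = segs.of_type(sse_type)
    type_traces = traces.of_type(sse_type)
    k = min(len(type_segs), len(type_traces))
    if k == 0:
        return [()]
    out = []
    for seg_subset in itertools.combinations(type_segs, k):
        for trace_perm in itertools.permutations(type_traces, k):
            for dirs in itertools.product(_DIRS, repeat=k):
                out.append(
                    tuple(
                        (s.id, tr.id, d)
                        for s, tr, d in zip(seg_subset, trace_perm, dirs)
                    )
                )
    return out


def enumerate_bruteforce(
    segs: SegmentSet,
    traces: TraceSet,
    skeleton: Optional[Skeleton] = None,
    cfg: DPConfig = DPConfig(),
    *,
    guard: int = 10**6,
    k_top: Optional[int] = None,
) -> List[RankedTopology]:
    """Score every valid topology; the exact reference for the DP ranker.

    Raises when the candidate space exceeds ``guard``.  Ties are broken by
    the lexicographic match-list key (segment position, trace position,
    forward before reverse).  Pass ``k_top`` to truncate the output; by
    default the full ranking is returned.
    """
    required = _required_per_type(segs, traces)
    if sum(required.values()) == 0:
        warnings.warn("no compatible segment/trace type pairs; no topologies")
        return []
    total = 1
    for t in (SSEType.HELIX, SSEType.STRAND):
        total *= count_topologies(len(segs.of_type(t)), len(traces.of_type(t)))
    if total > guard:
        raise InputError(
            f"candidate space has {total} topologies, exceeding the "
            f"enumeration guard of {guard}"
        )
    distances = TraceDistanceTable(traces, skeleton, cfg.distance_mode)
    helix_parts = _per_type_assignments(segs, traces, SSEType.HELIX)
    strand_parts = _per_type_assignments(segs, traces, SSEType.STRAND)
    seg_index = {s.id: k for k, s in enumerate(segs)}

    scored = []
    for hp, sp in itertools.product(helix_parts, strand_parts):
        entries = sorted(hp + sp, key=lambda e: seg_index[e[0]])
        topo = Topology(tuple(Match(*e) for e in entries))
        score = topology_score(
            topo, segs, traces, skeleton, cfg, distances=distances
        )
        scored.append((score, topo.sort_key(segs, traces), topo))
    scored.sort(key=lambda x: (x[0], x[1]))
    if k_top is not None:
        scored = scored[:k_top]
    return [
        RankedTopology(topo, score, rank + 1)
        for rank, (score, _key, topo) in enumerate(scored)
    ]


def rank_topologies_dp(
    segs: SegmentSet,
    traces: TraceSet,
    skeleton: Optional[Skeleton] = None,
    cfg: DPConfig = DPConfig(),
) -> List[RankedTopology]:
    """Top-k_top topologies by best-first search on the layered assignment graph.

    Nodes are (segment position, trace, direction) assignments plus skip
    nodes; paths respect increasing sequence order and at-most-once trace
    use.  Because every edge weight is non-negative, partial-path cost lower
    bounds every completion, so completions pop in non-decreasing score
    order and the search is exact: whenever full enumeration is feasible the
    returned list equals :func:`enumerate_bruteforce` truncated to ``k_top``,
    in both scores and membership.  Supports M ≥ N and M < N per type.
    """
    required = _required_per_type(segs, traces)
    if sum(required.values()) == 0:
        warnings.warn("no compatible segment/trace type pairs; no topologies")
        return []
    distances = TraceDistanceTable(traces, skeleton, cfg.distance_mode)
    skip_total = cfg.skip_penalty * _n_unmatched(segs, traces)

    seg_list = list(segs)
    n_segs = len(seg_list)
    trace_list = list(traces)
    type_trace_idx = {
        t: [k for k, tr in enumerate(trace_list) if tr.sse_type is t]
        for t in (SSEType.HELIX, SSEType.STRAND)
    }
    # suffix[i][type]: segments of that type at positions >= i
    suffix: List[Dict[SSEType, int]] = [
        {SSEType.HELIX: 0, SSEType.STRAND: 0} for _ in range(n_segs + 1)
    ]
    for i in range(n_segs - 1, -1, -1):
        for t in (SSEType.HELIX, SSEType.STRAND):
            suffix[i][t] = suffix[i + 1][t] + (1 if seg_list[i].sse_type is t else 0)

    type_key = {SSEType.HELIX: 0, SSEType.STRAND: 1}
    counter = itertools.count()
    # entry: (acc_cost, match_key, tiebreak, seg_pos, used_mask, (n_helix, n_strand))
    heap = [(0.0, (), next(counter), 0, 0, (0, 0))]
    results: List[Tuple[float, Tuple, Tuple]] = []
    k_top = cfg.k_top

    while heap:
        acc, key, _, pos, used, counts = heapq.heappop(heap)
        if len(results) >= k_top and acc + skip_total > results[k_top - 1][0]:
            break
        if pos == n_segs:
            results.append((acc + skip_total, key, key))
            continue
        seg = seg_list[pos]
        t = seg.sse_type
        matched_t = counts[type_key[t]]
        # skip this segment if enough segments of its type remain
        if suffix[pos + 1][t] >= required[t] - matched_t:
            heapq.heappush(heap, (acc, key, next(counter), pos + 1, used, counts))
        if matched_t < required[t]:
            last = key[-1] if key else None
            for j in type_trace_idx[t]:
                if used & (1 << j):
                    continue
                for d in _DIRS:
                    if last is None:
                        term = 0.0
                    else:
                        last_seg = seg_list[last[0]]
                        last_trace = trace_list[last[1]]
                        last_dir = _DIRS[last[2]]
                        loop = segs.loop_residues_between(last_seg, seg)
                        gap = distances.gap(
                            last_trace.id, last_dir, trace_list[j].id, d
                        )
                        term = _pair_term(gap, loop, cfg)
                    new_counts = (
                        (counts[0] + 1, counts[1])
                        if t is SSEType.HELIX
                        else (counts[0], counts[1] + 1)
                    )
                    heapq.heappush(
                        heap,
                        (
                            acc + term,
                            key + ((pos, j, d.order_key),),
                            next(counter),
                            pos + 1,
                            used | (1 << j),
                            new_counts,
                        ),
                    )

    results.sort(key=lambda x: (x[0], x[1]))
    results = results[:k_top]
    ranked = []
    for rank, (score, key, _) in enumerate(results):
        matches = tuple(
            Match(seg_list[si].id, trace_list[ti].id, _DIRS[df])
            for si, ti, df in key
        )
        ranked.append(RankedTopology(Topology(matches), score, rank + 1))
    return ranked
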
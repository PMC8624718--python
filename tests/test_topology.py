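import itertools

import numpy as np
import pytest

from ssetopo.model import (
    Direction,
    InputError,
    Match,
    SSEType,
    SegmentSet,
    SequenceSegment,
    Topology,
    Trace,
    TraceSet,
)
from ssetopo.synthetic import SyntheticSpec, make_case, random_instance
from ssetopo.topology import (
    DPConfig,
    count_topologies,
    enumerate_bruteforce,
    rank_topologies_dp,
    topology_score,
)

F, R = Direction.FORWARD, Direction.REVERSE


def _helix_segs(*bounds, seq_len=200):
    segs = tuple(
        SequenceSegment(f"S{k}", SSEType.HELIX, a, b) for k, (a, b) in enumerate(bounds)
    )
    return SegmentSet(segs, sequence_length=seq_len)


def _helix_traces(*pairs):
    return TraceSet(
        tuple(
            Trace(f"L{k}", SSEType.HELIX, np.asarray(a, float), np.asarray(b, float))
            for k, (a, b) in enumerate(pairs)
        )
    )


class TestCountTopologies:
    @pytest.mark.parametrize(
        "m, n, expected",
        [
            (1, 1, 2),     # one pairing, two directions
            (2, 1, 4),     # choose which segment is matched, two directions
            (5, 5, 3840),  # 5! orders x 2^5 directions
            (0, 3, 1),     # nothing matchable: the empty assignment
            (3, 5, count_topologies(5, 3)),  # symmetric in (m, n)
        ],
    )
    def test_formula(self, m, n, expected):
        assert count_topologies(m, n) == expected

    def test_enumeration_sizes_match_formula(self):
        # derived by exhaustive enumeration of pick x order x direction
        segs = _helix_segs((1, 5), (20, 24))
        traces = _helix_traces(([0, 0, 0], [8, 0, 0]))
        out = enumerate_bruteforce(segs, traces)
        assert len(out) == count_topologies(2, 1) == 4
        # each topology leaves exactly one segment unmatched
        for rt in out:
            assert len(rt.topology) == 1


class TestTopologyScore:
    def test_single_match_scores_only_skip_penalty(self):
        segs = _helix_segs((1, 5), (20, 24), (40, 44))
        traces = _helix_traces(([0, 0, 0], [8, 0, 0]))
        topo = Topology((Match("S1", "L0", F),))
        cfg = DPConfig(skip_penalty=10.0)
        assert topology_score(topo, segs, traces, None, cfg) == pytest.approx(20.0)

    def test_exact_loop_agreement_scores_zero(self):
        # collinear traces, endpoint gap 10 A; loop of 2 residues at a rise
        # of 5 A/residue predicts exactly 10 A
        segs = _helix_segs((1, 4), (7, 10), seq_len=20)
        traces = _helix_traces(([0, 0, 0], [10, 0, 0]), ([20, 0, 0], [30, 0, 0]))
        topo = Topology((Match("S0", "L0", F), Match("S1", "L1", F)))
        cfg = DPConfig(rise_per_residue=5.0, loop_slack=0.0)
        assert topology_score(topo, segs, traces, None, cfg) == pytest.approx(0.0)
        tight = DPConfig(rise_per_residue=1.0, loop_slack=0.0)
        assert topology_score(topo, segs, traces, None, tight) == pytest.approx(8.0)

    def test_reversed_direction_changes_the_observed_gap(self):
        segs = _helix_segs((1, 4), (7, 10), seq_len=20)
        traces = _helix_traces(([0, 0, 0], [10, 0, 0]), ([20, 0, 0], [30, 0, 0]))
        cfg = DPConfig(rise_per_residue=1.0, loop_slack=0.0)
        fwd = Topology((Match("S0", "L0", F), Match("S1", "L1", F)))
        rev = Topology((Match("S0", "L0", F), Match("S1", "L1", R)))
        # entering L1 from its far end lengthens the observed gap by 10 A
        assert topology_score(rev, segs, traces, None, cfg) == pytest.approx(
            topology_score(fwd, segs, traces, None, cfg) + 10.0
        )

    def test_type_mismatch_rejected(self):
        segs = _helix_segs((1, 4))
        traces = TraceSet(
            (Trace("L0", SSEType.STRAND, np.zeros(3), np.array([5.0, 0, 0])),)
        )
        with pytest.raises(InputError):
            topology_score(Topology((Match("S0", "L0", F),)), segs, traces)

    def test_true_three_helix_bundle_beats_all_47_alternatives(self):
        bundle = make_case(SyntheticSpec(n_helices=3, n_strands=0, seed=2))
        ranked = enumerate_bruteforce(
            bundle.segments, bundle.traces, bundle.skeleton, DPConfig()
        )
        assert len(ranked) == 48
        truth_matches = tuple(
            Match(s, *bundle.truth.pairs[s]) for s in sorted(bundle.truth.pairs)
        )
        assert ranked[0].topology == Topology(truth_matches)
        # the only candidate that can tie is the spatial mirror of the
        # bundle (reversed trace order, every direction flipped) -- loop
        # lengths alone cannot break that symmetry; everything else is
        # strictly worse
        mirror = Topology(
            tuple(
                Match(m.segment, rev.trace, Direction.REVERSE)
                for m, rev in zip(truth_matches, reversed(truth_matches))
            )
        )
        for rt in ranked[1:]:
            if rt.topology == mirror:
                continue
            assert rt.dp_score > ranked[0].dp_score


class TestRankTopologiesDP:
    def test_equals_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2024)
        cfg = DPConfig(k_top=100)
        for _ in range(25):
            segs, traces = random_instance(rng, max_per_type=4, max_candidates=20000)
            dp = rank_topologies_dp(segs, traces, None, cfg)
            bf = enumerate_bruteforce(segs, traces, None, cfg, k_top=100)
            assert [(r.dp_score, r.topology) for r in dp] == [
                (r.dp_score, r.topology) for r in bf
            ]
            assert [r.rank_init for r in dp] == list(range(1, len(dp) + 1))

    def test_k_top_one_returns_the_argmin(self):
        segs = _helix_segs((1, 5), (10, 14), (20, 24))
        traces = _helix_traces(
            ([0, 0, 0], [7, 0, 0]), ([12, 0, 0], [19, 0, 0]), ([24, 0, 0], [31, 0, 0])
        )
        full = enumerate_bruteforce(segs, traces)
        top1 = rank_topologies_dp(segs, traces, None, DPConfig(k_top=1))
        assert len(top1) == 1
        assert top1[0].topology == full[0].topology
        assert top1[0].dp_score == full[0].dp_score

    def test_scores_nondecreasing_and_size_bounded(self):
        bundle = make_case(SyntheticSpec(n_helices=4, seed=9))
        ranked = rank_topologies_dp(
            bundle.segments, bundle.traces, bundle.skeleton, DPConfig(k_top=60)
        )
        scores = [rt.dp_score for rt in ranked]
        assert scores == sorted(scores)
        assert len(ranked) <= 60
        assert len(ranked) <= count_topologies(4, 4)

    def test_more_traces_than_segments_supported(self):
        segs = _helix_segs((1, 5), (15, 19))
        traces = _helix_traces(
            ([0, 0, 0], [7, 0, 0]), ([12, 0, 0], [19, 0, 0]), ([40, 0, 0], [47, 0, 0])
        )
        ranked = rank_topologies_dp(segs, traces, None, DPConfig())
        assert len(ranked) == count_topologies(2, 3) == 24
        # every topology matches both segments; surplus traces stay unused
        assert all(len(rt.topology) == 2 for rt in ranked)

    def test_spurious_trace_leaves_other_scores_unchanged(self):
        segs = _helix_segs((1, 5), (15, 19))
        base = _helix_traces(([0, 0, 0], [7, 0, 0]), ([12, 0, 0], [19, 0, 0]))
        extra = TraceSet(
            base.traces
            + (Trace("L2", SSEType.HELIX, np.array([90.0, 0, 0]), np.array([95.0, 0, 0])),)
        )
        topo = Topology((Match("S0", "L0", F), Match("S1", "L1", F)))
        assert topology_score(topo, segs, base) == pytest.approx(
            topology_score(topo, segs, extra)
        )
        # and the candidate space only grows
        assert len(enumerate_bruteforce(segs, extra)) > len(
            enumerate_bruteforce(segs, base)
        )

    def test_no_compatible_types_warns_and_returns_empty(self):
        segs = _helix_segs((1, 5))
        traces = TraceSet(
            (Trace("L0", SSEType.STRAND, np.zeros(3), np.array([5.0, 0, 0])),)
        )
        with pytest.warns(UserWarning, match="no compatible"):
            assert rank_topologies_dp(segs, traces) == []

    def test_enumeration_guard_refuses_huge_spaces(self):
        bundle = make_case(SyntheticSpec(n_helices=6, seed=0))
        with pytest.raises(InputError, match="guard"):
            enumerate_bruteforce(
                bundle.segments, bundle.traces, bundle.skeleton, guard=100
            )
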
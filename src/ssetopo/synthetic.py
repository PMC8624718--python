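"""Self-contained synthetic test cases for the topology pipeline.

The generator lays an idealized up-down fold: helices packed side by side at
canonical inter-axis spacing, followed (optionally) by an antiparallel
β-sheet, with consecutive elements connected by loops whose residue counts
are consistent with the geometric gap at the stretched-backbone rate of
3.8 Å per residue.  From that one geometry it derives every input the
pipeline consumes:

* the amino-acid sequence (poly-alanine placeholder — no operation reads
  residue identity) and the true 3-state secondary-structure string;
* the true traces (helix axes, strand paths) and a skeleton sampled every
  1 Å along axes and loop paths;
* residue contacts: inter-element residue pairs whose idealized backbone
  positions lie within 8 Å (the conventional contact cutoff) receive high
  confidence, all other pairs low confidence, both with Gaussian noise;
* the ground-truth segment↔trace correspondence.

Corruption switches emulate the error modes seen in real predictions:
Gaussian jitter on trace endpoints, spurious or missing traces, a merge of
two predicted helices into one segment, and spurious short helix segments
at loop regions.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from . import io as tio
from .model import (
    ContactPair,
    Direction,
    GroundTruth,
    InputError,
    SSEType,
    SegmentSet,
    Skeleton,
    Trace,
    TraceSet,
)

__all__ = [
    "SyntheticSpec",
    "CaseBundle",
    "make_case",
    "write_case",
    "random_instance",
    "make_contact_rescue_case",
]

# idealized secondary-structure geometry
HELIX_RISE = 1.5  # Å per residue along the axis
HELIX_RADIUS = 2.3  # Å, backbone cylinder radius
HELIX_TWIST = math.radians(100.0)  # per residue
STRAND_RISE = 3.3  # Å per residue
LOOP_RISE_MAX = 3.8  # Å per residue, fully stretched loop
HELIX_SPACING = 10.5  # Å between packed helix axes
STRAND_SPACING = 4.8  # Å between strands in a sheet
MIXED_SPACING = 9.0  # Å between a helix axis and an adjacent strand
CONTACT_CUTOFF = 8.0  # Å, residue pairs closer than this are true contacts
P_HIGH = 0.9
P_LOW = 0.1
SKELETON_STEP = 1.0  # Å


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and corruption switches of one synthetic case."""

    n_helices: int = 4
    n_strands: int = 0
    helix_len_range: Tuple[int, int] = (9, 14)
    strand_len_range: Tuple[int, int] = (5, 7)
    loop_len_range: Tuple[int, int] = (2, 12)
    trace_jitter_sd: float = 0.0
    n_spurious_traces: int = 0
    n_missing_traces: int = 0
    merge_segments: bool = False
    n_spurious_segments: int = 0
    contact_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_helices,
            self.n_strands,
            self.n_spurious_traces,
            self.n_missing_traces,
            self.n_spurious_segments,
        )
        if any(c < 0 for c in counts):
            raise InputError("counts must be non-negative")
        for lo, hi in (
            self.helix_len_range,
            self.strand_len_range,
            self.loop_len_range,
        ):
            if lo > hi or lo < 1:
                raise InputError("length ranges must be non-empty and positive")
        if self.n_helices + self.n_strands < 1:
            raise InputError("need at least one secondary structure")


@dataclass
class CaseBundle:
    """Everything one pipeline run needs, from a single synthetic geometry."""

    spec: SyntheticSpec
    sequence: str
    ss_true: str
    ss: str  # after segment-level corruption
    segments: SegmentSet
    traces: TraceSet
    skeleton: Skeleton
    contacts: List[ContactPair]
    truth: GroundTruth
    residue_coords: np.ndarray  # (L, 3) idealized backbone positions


def _perp_frame(u: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _spacing(a: SSEType, b: SSEType) -> float:
    if a is SSEType.HELIX and b is SSEType.HELIX:
        return HELIX_SPACING
    if a is SSEType.STRAND and b is SSEType.STRAND:
        return STRAND_SPACING
    return MIXED_SPACING


def _sample_line(a: np.ndarray, b: np.ndarray, step: float) -> np.ndarray:
    length = float(np.linalg.norm(b - a))
    n = max(1, int(math.ceil(length / step)))
    ts = np.linspace(0.0, 1.0, n + 1)
    return a + ts[:, None] * (b - a)


def make_case(spec: SyntheticSpec) -> CaseBundle:
    """Generate a full synthetic case; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)

    # --- element shapes -------------------------------------------------
    types = [SSEType.HELIX] * spec.n_helices + [SSEType.STRAND] * spec.n_strands
    lengths = []
    for t in types:
        lo, hi = spec.helix_len_range if t is SSEType.HELIX else spec.strand_len_range
        lengths.append(int(rng.integers(lo, hi + 1)))

    # --- axis placement: up-down row ------------------------------------
    starts: List[np.ndarray] = []
    ends: List[np.ndarray] = []
    x = 0.0
    for k, (t, n_res) in enumerate(zip(types, lengths)):
        if k > 0:
            x += _spacing(types[k - 1], t)
        rise = HELIX_RISE if t is SSEType.HELIX else STRAND_RISE
        height = (n_res - 1) * rise
        bottom = np.array([x, 0.0, 0.0])
        top = np.array([x, 0.0, height])
        if k % 2 == 0:
            starts.append(bottom)
            ends.append(top)
        else:
            starts.append(top)
            ends.append(bottom)

    # --- loops consistent with the geometry ------------------------------
    loop_res: List[int] = []
    for k in range(len(types) - 1):
        gap = float(np.linalg.norm(starts[k + 1] - ends[k]))
        need = max(spec.loop_len_range[0], int(math.ceil(gap / LOOP_RISE_MAX)))
        if need > spec.loop_len_range[1]:
            raise InputError(
                f"loop between elements {k} and {k + 1} needs {need} residues, "
                f"outside loop_len_range {spec.loop_len_range}"
            )
        loop_res.append(need)

    # --- sequence, SS string, residue coordinates ------------------------
    ss_chars: List[str] = []
    coords: List[np.ndarray] = []
    intervals: List[Tuple[int, int]] = []  # 1-based inclusive, per element
    pos = 0
    for k, (t, n_res) in enumerate(zip(types, lengths)):
        a, b = starts[k], ends[k]
        u = (b - a) / np.linalg.norm(b - a)
        intervals.append((pos + 1, pos + n_res))
        if t is SSEType.HELIX:
            e1, e2 = _perp_frame(u)
            for r in range(n_res):
                angle = HELIX_TWIST * r
                coords.append(
                    a
                    + u * (HELIX_RISE * r)
                    + HELIX_RADIUS * (math.cos(angle) * e1 + math.sin(angle) * e2)
                )
            ss_chars.append("H" * n_res)
        else:
            for r in range(n_res):
                coords.append(a + u * (STRAND_RISE * r))
            ss_chars.append("E" * n_res)
        pos += n_res
        if k < len(types) - 1:
            n_loop = loop_res[k]
            for r in range(n_loop):
                frac = (r + 1) / (n_loop + 1)
                coords.append(ends[k] + frac * (starts[k + 1] - ends[k]))
            ss_chars.append("-" * n_loop)
            pos += n_loop
    ss_true = "".join(ss_chars)
    sequence = "A" * len(ss_true)
    residue_coords = np.array(coords)

    # --- skeleton ---------------------------------------------------------
    skel_parts = []
    for k in range(len(types)):
        skel_parts.append(_sample_line(starts[k], ends[k], SKELETON_STEP))
        if k < len(types) - 1:
            skel_parts.append(_sample_line(ends[k], starts[k + 1], SKELETON_STEP))
    skeleton = Skeleton(np.vstack(skel_parts), link_radius=3.0)

    # --- contacts ---------------------------------------------------------
    elem_of_res = np.full(len(sequence), -1)
    for e, (s, t_end) in enumerate(intervals):
        elem_of_res[s - 1 : t_end] = e
    dmat = cdist(residue_coords, residue_coords)
    contacts: List[ContactPair] = []
    for i in range(len(sequence)):
        for j in range(i + 1, len(sequence)):
            ei, ej = elem_of_res[i], elem_of_res[j]
            is_true = ei >= 0 and ej >= 0 and ei != ej and dmat[i, j] < CONTACT_CUTOFF
            base = P_HIGH if is_true else P_LOW
            p = float(np.clip(rng.normal(base, spec.contact_noise_sd), 0.0, 1.0))
            contacts.append(ContactPair(i + 1, j + 1, p))

    # --- segment-level corruption ----------------------------------------
    ss = list(ss_true)
    if spec.merge_segments and spec.n_helices >= 2:
        # fill the loop between the first two helices: two helices predicted
        # as one long segment
        s0_end = intervals[0][1]
        s1_start = intervals[1][0]
        for r in range(s0_end, s1_start - 1):
            ss[r] = "H"
    if spec.n_spurious_segments:
        # drop short helices into the longest loops, keeping a coil buffer
        loops = []
        for k in range(len(types) - 1):
            lo = intervals[k][1] + 1
            hi = intervals[k + 1][0] - 1
            if spec.merge_segments and k == 0:
                continue
            if hi - lo + 1 >= 5:
                loops.append((hi - lo + 1, lo, hi))
        loops.sort(reverse=True)
        for _, lo, hi in loops[: spec.n_spurious_segments]:
            mid = (lo + hi) // 2
            for r in (mid - 1, mid, mid + 1):
                ss[r - 1] = "H"
    ss = "".join(ss)
    segments = tio.parse_ss_string(sequence, ss)

    # --- trace-level corruption -------------------------------------------
    if spec.n_missing_traces > len(types):
        raise InputError("cannot remove more traces than exist")
    kept_elements = list(range(len(types)))
    for _ in range(spec.n_missing_traces):
        kept_elements.pop()  # drop from the C-terminal end
    trace_of_element: Dict[int, str] = {}
    trace_list: List[Trace] = []
    for e in kept_elements:
        a, b = starts[e].copy(), ends[e].copy()
        if spec.trace_jitter_sd > 0:
            a = a + rng.normal(0.0, spec.trace_jitter_sd, 3)
            b = b + rng.normal(0.0, spec.trace_jitter_sd, 3)
        tid = f"L{len(trace_list)}"
        trace_of_element[e] = tid
        trace_list.append(Trace(tid, types[e], a, b))
    bbox_lo = residue_coords.min(axis=0) - 8.0
    bbox_hi = residue_coords.max(axis=0) + 8.0
    for _ in range(spec.n_spurious_traces):
        center = rng.uniform(bbox_lo, bbox_hi)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        half = 2.5 * direction
        trace_list.append(
            Trace(f"L{len(trace_list)}", SSEType.HELIX, center - half, center + half)
        )
    traces = TraceSet(tuple(trace_list))

    # --- ground truth ------------------------------------------------------
    pairs: Dict[str, Tuple[str, Optional[Direction]]] = {}
    correct_segments = set()
    for seg in segments:
        overlapping = []
        for e, (s, t_end) in enumerate(intervals):
            ov = min(seg.end, t_end) - max(seg.start, s) + 1
            if ov > 0:
                overlapping.append((e, ov))
        if len(overlapping) != 1:
            continue  # merged or spurious segment: not a correct prediction
        e, ov = overlapping[0]
        ilen = intervals[e][1] - intervals[e][0] + 1
        if ov < 0.8 * ilen or ov < 0.8 * seg.length:
            continue
        if types[e] is not seg.sse_type:
            continue
        correct_segments.add(seg.id)
        if e in trace_of_element:
            pairs[seg.id] = (trace_of_element[e], Direction.FORWARD)
    correct_traces = frozenset(trace_of_element.values())
    truth = GroundTruth(pairs, frozenset(correct_segments), correct_traces)

    return CaseBundle(
        spec=spec,
        sequence=sequence,
        ss_true=ss_true,
        ss=ss,
        segments=segments,
        traces=traces,
        skeleton=skeleton,
        contacts=contacts,
        truth=truth,
        residue_coords=residue_coords,
    )


def write_case(bundle: CaseBundle, out_dir) -> Dict[str, Path]:
    """Write all case files in the tool formats; byte-identical per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "sequence": out / "sequence.fasta",
        "ss": out / "ss_prediction.txt",
        "traces": out / "traces.tsv",
        "skeleton": out / "skeleton.xyz",
        "contacts": out / "contacts.rr",
        "truth": out / "truth.tsv",
    }
    files["sequence"].write_text(f">synthetic case seed={bundle.spec.seed}\n{bundle.sequence}\n")
    files["ss"].write_text(bundle.ss + "\n")
    files["traces"].write_text(tio.write_traces(bundle.traces))
    files["skeleton"].write_text(tio.write_skeleton_xyz(bundle.skeleton))
    files["contacts"].write_text(tio.write_contacts_rr(bundle.contacts))
    files["truth"].write_text(tio.write_ground_truth(bundle.truth))
    return files


# ---------------------------------------------------------------------------
# auxiliary generators for exactness checks
# ---------------------------------------------------------------------------

def random_instance(
    rng: np.random.Generator,
    max_per_type: int = 4,
    max_candidates: int = 50_000,
    box: float = 50.0,
):
    """A random small (SegmentSet, TraceSet) pair for exhaustive checking.

    Segment and trace counts per type are drawn uniformly from
    [0, max_per_type] (re-drawn until at least one type has both a segment
    and a trace, and until the candidate space stays below
    ``max_candidates`` so exhaustive enumeration is practical).  Segments
    are laid consecutively with random lengths and gaps; trace endpoints
    are uniform in a cube of ``box`` Å.
    """
    from .model import SequenceSegment, SegmentSet, Trace, TraceSet
    from .topology import count_topologies

    while True:
        mh, ms = int(rng.integers(0, max_per_type + 1)), int(
            rng.integers(0, max_per_type + 1)
        )
        nh, ns = int(rng.integers(0, max_per_type + 1)), int(
            rng.integers(0, max_per_type + 1)
        )
        if min(mh, nh) + min(ms, ns) == 0:
            continue
        if count_topologies(mh, nh) * count_topologies(ms, ns) > max_candidates:
            continue
        break

    seg_types = [SSEType.HELIX] * mh + [SSEType.STRAND] * ms
    rng.shuffle(seg_types)
    segments = []
    pos = 1
    for k, t in enumerate(seg_types):
        lo = 3 if t is SSEType.HELIX else 1
        length = int(rng.integers(lo, lo + 8))
        segments.append(SequenceSegment(f"S{k}", t, pos, pos + length - 1))
        pos += length + int(rng.integers(1, 12))
    segs = SegmentSet(tuple(segments), sequence_length=pos + 5)

    traces = []
    trace_types = [SSEType.HELIX] * nh + [SSEType.STRAND] * ns
    rng.shuffle(trace_types)
    for k, t in enumerate(trace_types):
        while True:
            a = rng.uniform(0.0, box, 3)
            b = rng.uniform(0.0, box, 3)
            if np.linalg.norm(b - a) > 2.0:
                break
        traces.append(Trace(f"L{k}", t, a, b))
    return segs, TraceSet(tuple(traces))


def make_contact_rescue_case(
    n_helices: int = 5,
    helix_len: int = 10,
    loop_len: int = 15,
    spacing: float = 10.0,
    trace_labels: Optional[Sequence[int]] = None,
):
    """A synthetic case whose geometry cannot order the helices but whose
    contacts can.

    All helices stand parallel in a row at ``spacing`` Å; the loops are long
    enough (``loop_len`` residues at 3.8 Å/residue) that every candidate
    topology satisfies the loop-length constraint, so the initial geometric
    ranking degenerates to its deterministic tie-break and the true topology
    lands mid-list.  Contacts connect sequence-adjacent helices, which only
    row-adjacent trace pairs (< 13 Å apart) can satisfy, so contact-based
    re-ranking pulls the true topology up.

    ``trace_labels[r]`` gives the numeric trace label of the helix at row
    position ``r``; the default scrambles labels so the true topology's
    tie-break position is mid-list rather than first.

    Returns ``(segments, traces, ss_contacts, truth)``.
    """
    from .model import (
        GroundTruth,
        SSContactPair,
        SequenceSegment,
        SegmentSet,
        Trace,
        TraceSet,
    )

    if trace_labels is None:
        # deterministic scramble so the true assignment is lexicographically
        # mid-list rather than first
        trace_labels = [(r * 2 + n_helices // 2) % n_helices for r in range(n_helices)]
        if len(set(trace_labels)) != n_helices:
            trace_labels = list(reversed(range(n_helices)))
            mid = n_helices // 2
            trace_labels[0], trace_labels[mid] = trace_labels[mid], trace_labels[0]
    if sorted(trace_labels) != list(range(n_helices)):
        raise InputError("trace_labels must be a permutation of 0..n_helices-1")

    height = (helix_len - 1) * HELIX_RISE
    segments = []
    pos = 1
    for k in range(n_helices):
        segments.append(SequenceSegment(f"S{k}", SSEType.HELIX, pos, pos + helix_len - 1))
        pos += helix_len + loop_len
    segs = SegmentSet(tuple(segments), sequence_length=pos)

    trace_list = [None] * n_helices
    for row, label in enumerate(trace_labels):
        a = np.array([row * spacing, 0.0, 0.0])
        b = np.array([row * spacing, 0.0, height])
        trace_list[label] = Trace(f"L{label}", SSEType.HELIX, a, b)
    traces = TraceSet(tuple(trace_list))

    ss_contacts = [
        SSContactPair(f"S{k}", f"S{k + 1}", 3) for k in range(n_helices - 1)
    ]
    pairs = {
        f"S{k}": (f"L{trace_labels[k]}", Direction.FORWARD) for k in range(n_helices)
    }
    truth = GroundTruth(
        pairs,
        frozenset(pairs),
        frozenset(t.id for t in trace_list),
    )
    return segs, traces, ss_contacts, truth
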
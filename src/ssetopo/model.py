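"""Domain types for secondary-structure topology ranking.

The central objects are:

* :class:`SequenceSegment` / :class:`SegmentSet` — helix/strand segments
  predicted on the protein sequence (1D information).
* :class:`Trace` / :class:`TraceSet` — straight 3D line segments standing for
  helix axes (α-traces) and strand paths (β-traces) detected in a density map
  (3D information).
* :class:`ContactPair` / :class:`SSContactPair` — predicted residue-residue
  contacts and their aggregation to pairs of sequence segments (2D
  information).
* :class:`Topology` — an ordered, directed assignment of segments to traces
  from the N- to the C-terminus.
* :class:`RankedTopology` — a topology carrying its geometric score, its
  initial rank, contact-satisfaction counts and the fused re-ranking score.

Residue indices are 1-based and inclusive throughout, matching PDB and CASP
RR conventions.  Coordinates are in Ångström.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SSEType",
    "Direction",
    "SequenceSegment",
    "SegmentSet",
    "Trace",
    "TraceSet",
    "ContactPair",
    "SSContactPair",
    "Match",
    "Topology",
    "RankedTopology",
    "Skeleton",
    "GroundTruth",
    "ScreeningConfig",
    "InputError",
]


class InputError(ValueError):
    """Raised when an input file or in-memory object violates the format."""


class SSEType(str, enum.Enum):
    """Secondary-structure element class: α-helix or β-strand."""

    HELIX = "H"
    STRAND = "E"

    @classmethod
    def from_label(cls, label: str) -> "SSEType":
        label = label.strip().upper()
        if label in ("H", "HELIX", "A", "ALPHA"):
            return cls.HELIX
        if label in ("E", "STRAND", "B", "BETA"):
            return cls.STRAND
        raise InputError(f"unknown secondary-structure type {label!r}")


class Direction(str, enum.Enum):
    """Alignment direction of a trace with respect to the sequence.

    A trace L may be aligned N→C either from p_start to p_end (``FORWARD``,
    written ``+``) or from p_end to p_start (``REVERSE``, written ``-``, the
    primed direction L′).
    """

    FORWARD = "+"
    REVERSE = "-"

    @classmethod
    def from_symbol(cls, sym: str) -> "Direction":
        sym = sym.strip()
        if sym in ("+", "f", "forward"):
            return cls.FORWARD
        if sym in ("-", "r", "reverse", "'"):
            return cls.REVERSE
        raise InputError(f"unknown direction symbol {sym!r}")

    @property
    def order_key(self) -> int:
        """Deterministic sort key; forward sorts before reverse."""
        return 0 if self is Direction.FORWARD else 1


MIN_HELIX_RESIDUES = 3  # predicted helices shorter than this are ignored


@dataclass(frozen=True)
class SequenceSegment:
    """A predicted secondary-structure segment on the sequence.

    ``start`` and ``end`` are 1-based inclusive residue indices.
    """

    id: str
    sse_type: SSEType
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(
                f"segment {self.id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise InputError(f"segment {self.id}: residue indices are 1-based")
        if self.sse_type is SSEType.HELIX and self.length < MIN_HELIX_RESIDUES:
            raise InputError(
                f"segment {self.id}: helices shorter than "
                f"{MIN_HELIX_RESIDUES} residues are not valid segments"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, residue: int) -> bool:
        return self.start <= residue <= self.end


@dataclass(frozen=True)
class SegmentSet:
    """Ordered, non-overlapping segments S0…S(M−1) along one chain."""

    segments: Tuple[SequenceSegment, ...]
    sequence_length: int

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        prev_end = 0
        for k, seg in enumerate(segs):
            if seg.id != f"S{k}":
                raise InputError(
                    f"segment ids must be consecutive S0…; got {seg.id} at {k}"
                )
            if seg.start <= prev_end:
                raise InputError(
                    f"segment {seg.id} overlaps or is out of order "
                    f"(starts at {seg.start}, previous ends at {prev_end})"
                )
            prev_end = seg.end
        if segs and segs[-1].end > self.sequence_length:
            raise InputError("segment extends beyond sequence length")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[SequenceSegment]:
        return iter(self.segments)

    def __getitem__(self, index: int) -> SequenceSegment:
        return self.segments[index]

    def by_id(self, seg_id: str) -> SequenceSegment:
        for seg in self.segments:
            if seg.id == seg_id:
                return seg
        raise KeyError(seg_id)

    def index_of(self, seg_id: str) -> int:
        for k, seg in enumerate(self.segments):
            if seg.id == seg_id:
                return k
        raise KeyError(seg_id)

    def segment_of_residue(self, residue: int) -> Optional[SequenceSegment]:
        """The segment containing ``residue``, or None if it lies in a loop."""
        for seg in self.segments:
            if seg.contains(residue):
                return seg
        return None

    def of_type(self, sse_type: SSEType) -> Tuple[SequenceSegment, ...]:
        return tuple(s for s in self.segments if s.sse_type is sse_type)

    def loop_residues_between(self, a: SequenceSegment, b: SequenceSegment) -> int:
        """Number of residues strictly between two segments (a before b).

        Residues of any skipped segment lying between them are counted as
        loop residues, which is how unmatched segments contribute to the
        expected loop length of the enclosing connection.
        """
        if a.end >= b.start:
            raise ValueError("segments are not in increasing sequence order")
        return b.start - a.end - 1


Point = np.ndarray  # shape (3,), float


def _as_point(p: Sequence[float]) -> Point:
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise InputError(f"expected a 3D point, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Trace:
    """A straight 3D line segment for one detected secondary structure."""

    id: str
    sse_type: SSEType
    p_start: Point
    p_end: Point

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_start", _as_point(self.p_start))
        object.__setattr__(self, "p_end", _as_point(self.p_end))
        if self.length <= 0.0:
            raise InputError(f"trace {self.id}: zero-length trace")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p_end - self.p_start))

    def entry_point(self, direction: Direction) -> Point:
        """The endpoint at which the sequence enters the trace (N-side)."""
        return self.p_start if direction is Direction.FORWARD else self.p_end

    def exit_point(self, direction: Direction) -> Point:
        """The endpoint at which the sequence leaves the trace (C-side)."""
        return self.p_end if direction is Direction.FORWARD else self.p_start


@dataclass(frozen=True)
class TraceSet:
    """All traces detected in one density map."""

    traces: Tuple[Trace, ...]

    def __post_init__(self) -> None:
        trs = tuple(self.traces)
        object.__setattr__(self, "traces", trs)
        ids = [t.id for t in trs]
        if len(set(ids)) != len(ids):
            raise InputError("trace ids must be unique")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[Trace]:
        return iter(self.traces)

    def by_id(self, trace_id: str) -> Trace:
        for tr in self.traces:
            if tr.id == trace_id:
                return tr
        raise KeyError(trace_id)

    def index_of(self, trace_id: str) -> int:
        for k, tr in enumerate(self.traces):
            if tr.id == trace_id:
                return k
        raise KeyError(trace_id)

    def of_type(self, sse_type: SSEType) -> Tuple[Trace, ...]:
        return tuple(t for t in self.traces if t.sse_type is sse_type)


@dataclass(frozen=True)
class ContactPair:
    """A predicted residue-residue contact with confidence p ∈ [0, 1]."""

    i: int
    j: int
    p: float

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise InputError(f"contact ({self.i},{self.j}): require i < j")
        if not (0.0 <= self.p <= 1.0):
            raise InputError(f"contact ({self.i},{self.j}): p={self.p} outside [0,1]")

    @property
    def separation(self) -> int:
        """Residues strictly between the two partners."""
        return self.j - self.i - 1


@dataclass(frozen=True)
class SSContactPair:
    """A pair of sequence segments supported by predicted residue contacts."""

    seg_a: str
    seg_b: str
    n_pairs: int

    def __post_init__(self) -> None:
        if self.seg_a == self.seg_b:
            raise InputError("a segment cannot be in contact with itself")
        if self.n_pairs < 1:
            raise InputError("n_pairs must be >= 1")


@dataclass(frozen=True)
class Match:
    """One (segment, trace, direction) assignment within a topology."""

    segment: str
    trace: str
    direction: Direction


@dataclass(frozen=True)
class Topology:
    """An ordered list of matches from the N- to the C-terminus.

    Segment ids appear in strictly increasing sequence order, each trace is
    used at most once, and segment/trace types agree per match.  Validity
    against a concrete :class:`SegmentSet` / :class:`TraceSet` is checked by
    :meth:`validate`.
    """

    matches: Tuple[Match, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "matches", tuple(self.matches))
        traces = [m.trace for m in self.matches]
        if len(set(traces)) != len(traces):
            raise InputError("a trace may be used at most once in a topology")

    def __len__(self) -> int:
        return len(self.matches)

    def __iter__(self) -> Iterator[Match]:
        return iter(self.matches)

    def matched_segments(self) -> Tuple[str, ...]:
        return tuple(m.segment for m in self.matches)

    def trace_of(self, seg_id: str) -> Optional[Tuple[str, Direction]]:
        for m in self.matches:
            if m.segment == seg_id:
                return (m.trace, m.direction)
        return None

    def validate(self, segs: SegmentSet, traces: TraceSet) -> None:
        prev_idx = -1
        n_matched_by_type = {SSEType.HELIX: 0, SSEType.STRAND: 0}
        for m in self.matches:
            seg = segs.by_id(m.segment)
            tr = traces.by_id(m.trace)
            idx = segs.index_of(m.segment)
            if idx <= prev_idx:
                raise InputError("matches must follow increasing sequence order")
            prev_idx = idx
            if seg.sse_type is not tr.sse_type:
                raise InputError(
                    f"type mismatch: {m.segment} is {seg.sse_type.name}, "
                    f"{m.trace} is {tr.sse_type.name}"
                )
            n_matched_by_type[seg.sse_type] += 1
        for sse_type, count in n_matched_by_type.items():
            expected = min(len(segs.of_type(sse_type)), len(traces.of_type(sse_type)))
            if count != expected:
                raise InputError(
                    f"{sse_type.name}: topology matches {count} elements, "
                    f"expected min(M, N) = {expected}"
                )

    def sort_key(self, segs: SegmentSet, traces: TraceSet) -> Tuple:
        """Deterministic lexicographic key over the match list.

        Orders by segment position, then trace position, then direction
        (forward before reverse); used to break score ties reproducibly.
        """
        return tuple(
            (segs.index_of(m.segment), traces.index_of(m.trace), m.direction.order_key)
            for m in self.matches
        )


@dataclass
class RankedTopology:
    """A topology with its geometric score, ranks, and contact counts.

    ``rank_init`` is the 1-based position in the initial geometry-only
    ranking; ``cp``/``sp`` count contact-supported segment pairs whose traces
    are both assigned, and the subset of those lying within the contact
    distance threshold; ``rank_update`` is the position after sorting by
    SP/CP; ``fused_score`` is the weighted rank combination
    a·rank_init + (1−a)·rank_update.
    """

    topology: Topology
    dp_score: float
    rank_init: int
    cp: Optional[int] = None
    sp: Optional[int] = None
    rank_update: Optional[int] = None
    fused_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rank_init < 1:
            raise InputError("rank_init is 1-based and must be >= 1")
        if self.cp is not None and self.sp is not None:
            if not (0 <= self.sp <= self.cp):
                raise InputError("require 0 <= sp <= cp")

    @property
    def contact_ratio(self) -> float:
        """SP/CP, with the convention that CP = 0 yields ratio 0."""
        if not self.cp:
            return 0.0
        return self.sp / self.cp


@dataclass(frozen=True)
class Skeleton:
    """A thin point-set representation of the density map's connectivity."""

    points: np.ndarray  # (n, 3)
    link_radius: float = 3.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InputError("skeleton points must be an (n, 3) array")
        object.__setattr__(self, "points", pts)
        if self.link_radius <= 0:
            raise InputError("link_radius must be positive")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class GroundTruth:
    """The segment↔trace correspondence derived from an atomic structure.

    ``pairs`` maps a correctly predicted segment to its correct trace and
    direction; a ``None`` direction marks a direction-agnostic pair (used for
    very short traces whose orientation cannot be meaningfully assessed).
    """

    pairs: Mapping[str, Tuple[str, Optional[Direction]]]
    correct_segments: frozenset
    correct_traces: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", dict(self.pairs))
        object.__setattr__(self, "correct_segments", frozenset(self.correct_segments))
        object.__setattr__(self, "correct_traces", frozenset(self.correct_traces))
        for seg, (trace, _d) in self.pairs.items():
            if seg not in self.correct_segments:
                raise InputError(f"truth pair segment {seg} not in correct_segments")
            if trace not in self.correct_traces:
                raise InputError(f"truth pair trace {trace} not in correct_traces")


@dataclass(frozen=True)
class ScreeningConfig:
    """Parameters of the significant long-range contact screen.

    ``min_separation`` counts residues strictly between the contact partners;
    a contact is short-range (and dropped) when that count is
    <= ``min_separation``.  ``sd_levels`` is the cascade of standard-deviation
    multipliers tried in order; the cascade stops at the first level that
    yields at least ``min_ss_pairs_to_stop`` distinct segment pairs.
    """

    near_zero_eps: float = 0.001
    min_separation: int = 3
    sd_levels: Tuple[float, ...] = (3.0, 2.0, 1.0)
    min_ss_pairs_to_stop: int = 2

    def __post_init__(self) -> None:
        if self.near_zero_eps < 0:
            raise InputError("near_zero_eps must be >= 0")
        levels = tuple(self.sd_levels)
        object.__setattr__(self, "sd_levels", levels)
        if any(b >= a for a, b in zip(levels, levels[1:])):
            raise InputError("sd_levels must be strictly decreasing")
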
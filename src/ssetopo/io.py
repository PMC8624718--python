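"""Readers and writers for all tool formats.

All formats are plain text, tab- or whitespace-separated, with ``#`` comment
lines.  Residue indexing is 1-based inclusive; coordinates are in Ångström
and written with three decimals.

Formats
-------
sequence
    FASTA (read via Biopython).
secondary-structure prediction
    A 3-state string aligned to the sequence: ``H`` helix, ``E`` strand,
    anything else coil.  A single optional ``>`` header line is tolerated.
contacts
    CASP RR dialect: ``i j d1 d2 p`` or the short form ``i j p``.
traces
    ``id  type{H|E}  x1 y1 z1  x2 y2 z2``.
skeleton
    XYZ text, one ``x y z`` point per line.
ground truth
    Pair lines ``segment_id  trace_id  direction{+|-|*}`` (``*`` =
    direction-agnostic) plus directives ``#correct_segments`` and
    ``#correct_traces`` listing ids that are correctly predicted.
topology table
    ``rank  dp_score  cp  sp  fused_score  Si:Lj:+ ...`` with ``-`` for
    fields that are not yet computed.
"""

from __future__ import annotations

import io as _io
import os
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple, Union

import numpy as np
from Bio import SeqIO

from .model import (
    ContactPair,
    Direction,
    GroundTruth,
    InputError,
    MIN_HELIX_RESIDUES,
    Match,
    RankedTopology,
    SSContactPair,
    SSEType,
    SegmentSet,
    SequenceSegment,
    Skeleton,
    Topology,
    TraceSet,
    Trace,
)

__all__ = [
    "parse_ss_string",
    "segments_to_ss_string",
    "read_fasta",
    "read_ss_prediction",
    "read_contacts_rr",
    "write_contacts_rr",
    "read_traces",
    "write_traces",
    "read_skeleton_xyz",
    "write_skeleton_xyz",
    "read_ground_truth",
    "write_ground_truth",
    "read_ss_contacts",
    "write_ss_contacts",
    "read_topologies",
    "write_topologies",
]

PathOrText = Union[str, os.PathLike]

# Optional alias table folding 8-state DSSP-style codes onto 3 states.
DSSP_ALIASES = {"G": "H", "I": "H", "B": "E"}


def _lines(source: Union[str, TextIO]) -> List[str]:
    if hasattr(source, "read"):
        return source.read().splitlines()
    text = str(source)
    if "\n" not in text and os.path.exists(text):
        with open(text) as fh:
            return fh.read().splitlines()
    return text.splitlines()


# ---------------------------------------------------------------------------
# sequence and secondary-structure strings
# ---------------------------------------------------------------------------

def read_fasta(path: PathOrText) -> str:
    """Return the first sequence in a FASTA file as an uppercase string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return str(records[0].seq).upper()


def read_ss_prediction(source: Union[str, TextIO]) -> str:
    """Read a 3-state secondary-structure string, ignoring headers/comments."""
    parts = []
    for line in _lines(source):
        line = line.strip()
        if not line or line.startswith(("#", ">")):
            continue
        parts.append(line)
    return "".join(parts)


def parse_ss_string(
    sequence: str,
    ss: str,
    *,
    aliases: Optional[Dict[str, str]] = None,
) -> SegmentSet:
    """Extract secondary-structure segments from a 3-state string.

    Maximal runs of ``H`` become helix segments, maximal runs of ``E`` strand
    segments; every other symbol is coil.  Predicted helices shorter than
    three residues are ignored (a convention of sequence-based predictors for
    which one- or two-residue helices are not meaningful); strands of any
    length are kept.  Ids are assigned S0, S1, … in order of start position.

    Parameters
    ----------
    sequence : str
        Amino-acid sequence, used only for its length.
    ss : str
        3-state string of the same length.  Alphabet ``{H, E}`` plus
        anything-else-is-coil; pass ``aliases`` (e.g. ``DSSP_ALIASES``) to
        fold 8-state codes onto the 3 states.
    """
    if len(ss) != len(sequence):
        raise InputError(
            f"secondary-structure string length {len(ss)} != "
            f"sequence length {len(sequence)}"
        )
    alias = aliases or {}
    states = []
    for ch in ss.upper():
        ch = alias.get(ch, ch)
        if ch in ("H", "E"):
            states.append(ch)
        elif ch.isalpha() or ch in ("-", ".", " ", "C"):
            states.append("-")
        else:
            raise InputError(f"unknown secondary-structure symbol {ch!r}")

    segments: List[SequenceSegment] = []
    run_start = None
    run_state = "-"

    def close_run(end_idx: int) -> None:
        nonlocal run_start, run_state
        if run_start is None or run_state == "-":
            return
        start, end = run_start + 1, end_idx + 1  # to 1-based inclusive
        length = end - start + 1
        if run_state == "H" and length < MIN_HELIX_RESIDUES:
            return
        sse = SSEType.HELIX if run_state == "H" else SSEType.STRAND
        segments.append(
            SequenceSegment(f"S{len(segments)}", sse, start, end)
        )

    for idx, state in enumerate(states):
        if state != run_state:
            close_run(idx - 1)
            run_start, run_state = idx, state
    close_run(len(states) - 1)
    return SegmentSet(tuple(segments), sequence_length=len(sequence))


def segments_to_ss_string(segs: SegmentSet) -> str:
    """Serialize a SegmentSet back to a 3-state string (loops as '-')."""
    out = ["-"] * segs.sequence_length
    for seg in segs:
        ch = "H" if seg.sse_type is SSEType.HELIX else "E"
        for r in range(seg.start, seg.end + 1):
            out[r - 1] = ch
    return "".join(out)


# ---------------------------------------------------------------------------
# residue contacts (CASP RR dialect)
# ---------------------------------------------------------------------------

def read_contacts_rr(source: Union[str, TextIO]) -> List[ContactPair]:
    """Parse residue contacts from CASP RR-style text.

    Accepts ``i j d1 d2 p`` (full RR) or ``i j p`` lines; header and comment
    lines are tolerated.  Pairs are normalized to i < j; duplicate pairs keep
    the maximum confidence.
    """
    best: Dict[Tuple[int, int], float] = {}
    for line in _lines(source):
        line = line.strip()
        if not line or line.startswith(("#", ">")):
            continue
        fields = line.split()
        if fields[0].isalpha():
            continue  # PFRMAT/TARGET/MODEL header words, or a sequence line
        if len(fields) < 3:
            raise InputError(f"malformed contact line: {line!r}")
        try:
            i, j = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise InputError(f"non-integer residue index in: {line!r}") from exc
        try:
            p = float(fields[4] if len(fields) >= 5 else fields[2])
        except ValueError as exc:
            raise InputError(f"malformed confidence in: {line!r}") from exc
        if not (0.0 <= p <= 1.0):
            raise InputError(f"confidence {p} outside [0,1] in: {line!r}")
        if i == j:
            raise InputError(f"self-contact ({i},{j}) is not allowed")
        if i > j:
            i, j = j, i
        key = (i, j)
        if key not in best or p > best[key]:
            best[key] = p
    return [ContactPair(i, j, p) for (i, j), p in sorted(best.items())]


def write_contacts_rr(contacts: Iterable[ContactPair]) -> str:
    lines = ["# i j d1 d2 p"]
    for c in contacts:
        lines.append(f"{c.i} {c.j} 0 8 {c.p:.6f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def read_traces(source: Union[str, TextIO]) -> TraceSet:
    """Read traces from tab-separated ``id type x1 y1 z1 x2 y2 z2`` text."""
    traces: List[Trace] = []
    for line in _lines(source):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 8:
            raise InputError(f"malformed trace line: {line!r}")
        trace_id = fields[0]
        sse_type = SSEType.from_label(fields[1])
        coords = [float(x) for x in fields[2:]]
        p_start = np.array(coords[:3])
        p_end = np.array(coords[3:])
        if np.allclose(p_start, p_end):
            raise InputError(f"trace {trace_id}: p_start equals p_end")
        traces.append(Trace(trace_id, sse_type, p_start, p_end))
    return TraceSet(tuple(traces))


def write_traces(traces: TraceSet) -> str:
    lines = ["#id\ttype\tx1\ty1\tz1\tx2\ty2\tz2"]
    for t in traces:
        xyz = "\t".join(f"{v:.3f}" for v in (*t.p_start, *t.p_end))
        lines.append(f"{t.id}\t{t.sse_type.value}\t{xyz}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# skeleton
# ---------------------------------------------------------------------------

def read_skeleton_xyz(source: Union[str, TextIO], link_radius: float = 3.0) -> Skeleton:
    pts = []
    for line in _lines(source):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise InputError(f"malformed skeleton point line: {line!r}")
        pts.append([float(x) for x in fields])
    if not pts:
        raise InputError("empty skeleton file")
    return Skeleton(np.array(pts), link_radius=link_radius)


def write_skeleton_xyz(skeleton: Skeleton) -> str:
    lines = [f"{x:.3f}\t{y:.3f}\t{z:.3f}" for x, y, z in skeleton.points]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def read_ground_truth(source: Union[str, TextIO]) -> GroundTruth:
    pairs: Dict[str, Tuple[str, Optional[Direction]]] = {}
    correct_segments: set = set()
    correct_traces: set = set()
    for line in _lines(source):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#correct_segments"):
            correct_segments.update(line.split()[1:])
            continue
        if line.startswith("#correct_traces"):
            correct_traces.update(line.split()[1:])
            continue
        if line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise InputError(f"malformed ground-truth line: {line!r}")
        seg_id, trace_id, dsym = fields
        direction = None if dsym == "*" else Direction.from_symbol(dsym)
        pairs[seg_id] = (trace_id, direction)
        correct_segments.add(seg_id)
        correct_traces.add(trace_id)
    return GroundTruth(pairs, frozenset(correct_segments), frozenset(correct_traces))


def write_ground_truth(truth: GroundTruth) -> str:
    lines = [
        "#segment_id\ttrace_id\tdirection",
        "#correct_segments " + " ".join(sorted(truth.correct_segments)),
        "#correct_traces " + " ".join(sorted(truth.correct_traces)),
    ]
    for seg_id in sorted(truth.pairs, key=lambda s: int(s.lstrip("S"))):
        trace_id, direction = truth.pairs[seg_id]
        dsym = "*" if direction is None else direction.value
        lines.append(f"{seg_id}\t{trace_id}\t{dsym}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# secondary-structure contact table
# ---------------------------------------------------------------------------

def write_ss_contacts(
    ss_pairs: Iterable[SSContactPair], segs: Optional[SegmentSet] = None
) -> str:
    """Write SS contact pairs as ``Sa Sb typeA typeB n_pairs``."""

    def type_label(seg_id: str) -> str:
        if segs is None:
            return "?"
        seg = segs.by_id(seg_id)
        return "a" if seg.sse_type is SSEType.HELIX else "b"

    lines = ["#seg_a\tseg_b\ttype_a\ttype_b\tn_pairs"]
    for pair in ss_pairs:
        lines.append(
            f"{pair.seg_a}\t{pair.seg_b}\t{type_label(pair.seg_a)}\t"
            f"{type_label(pair.seg_b)}\t{pair.n_pairs}"
        )
    return "\n".join(lines) + "\n"


def read_ss_contacts(source: Union[str, TextIO]) -> List[SSContactPair]:
    pairs = []
    for line in _lines(source):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) not in (3, 5):
            raise InputError(f"malformed SS contact line: {line!r}")
        pairs.append(SSContactPair(fields[0], fields[1], int(fields[-1])))
    return pairs


# ---------------------------------------------------------------------------
# topology tables
# ---------------------------------------------------------------------------

def _fmt_opt(value, spec: str = "") -> str:
    return "-" if value is None else format(value, spec)


def write_topologies(ranked: Sequence[RankedTopology]) -> str:
    lines = ["#rank\tdp_score\tcp\tsp\tfused_score\tmatches"]
    for rt in ranked:
        matches = " ".join(
            f"{m.segment}:{m.trace}:{m.direction.value}" for m in rt.topology.matches
        )
        lines.append(
            f"{rt.rank_init}\t{rt.dp_score:.4f}\t{_fmt_opt(rt.cp)}\t"
            f"{_fmt_opt(rt.sp)}\t{_fmt_opt(rt.fused_score, '.2f')}\t{matches}"
        )
    return "\n".join(lines) + "\n"


def read_topologies(source: Union[str, TextIO]) -> List[RankedTopology]:
    out: List[RankedTopology] = []
    for line in _lines(source):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise InputError(f"malformed topology line: {line!r}")
        rank_init = int(fields[0])
        dp_score = float(fields[1])
        cp = None if fields[2] == "-" else int(fields[2])
        sp = None if fields[3] == "-" else int(fields[3])
        fused = None if fields[4] == "-" else float(fields[4])
        matches = []
        if len(fields) > 5 and fields[5].strip():
            for token in fields[5].split():
                seg_id, trace_id, dsym = token.split(":")
                matches.append(Match(seg_id, trace_id, Direction.from_symbol(dsym)))
        out.append(
            RankedTopology(
                Topology(tuple(matches)), dp_score, rank_init, cp=cp, sp=sp,
                fused_score=fused,
            )
        )
    return out
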
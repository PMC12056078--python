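"""Reference-guided reconstruction of a circular element from duplicated
segments plus long-read junction evidence.

The reconstruction is deliberately not a de novo assembly: the duplicated
segments are already known from coverage, so the only unknowns are (a) which
segment ends are adjacent on the circle and in which orientation, and (b) the
exact base position of each adjacency.  The stages are:

1. ``enumerate_candidates`` — every oriented adjacency joining a segment end
   to a segment start (self-joins and fold-backs included), deduplicated up
   to reverse complement; candidates whose 2k-mer occurs in the reference are
   flagged as reference adjacencies and excluded from circle resolution.
2. ``refine_junction_flanks`` — depth-called boundaries carry bin-scale
   error, which would make the candidate 2k-mer miss every read.  Junction-
   spanning reads are located by an anchor pair (one interior anchor per
   segment side at a plausible spacing), and each flank offset is then moved
   to the position that maximizes junction read support: probes sliding past
   the true breakpoint stop matching junction reads, so support is a step
   function whose edge is the breakpoint.
3. ``score_candidates`` — one pass of the read set per candidate junction.
4. ``resolve_layout`` — greedy acceptance of the best-supported adjacencies
   into a single Hamiltonian cycle over the segments, with explicit
   ambiguity and incompleteness errors.
5. ``assemble_circle`` — orientation-adjusted concatenation of the refined
   segment sequences; the result can be rotated to any anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import edlib

from . import junctions as _junctions
from .circles import CircleLayout, ReconstructedCircle
from .errors import (
    AmbiguousLayoutError,
    IncompleteCircleError,
    InvalidParameterError,
)
from .intervals import Segment
from .io import load_reads
from .junctions import JunctionSpec, MatchParams, _matches
from .sequences import revcomp


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _tail_flank(ref: str, seg: Segment, strand: str, k: int, shift: int = 0) -> str | None:
    """Last ``k`` bases of the oriented segment, its oriented end moved by ``shift``."""
    if strand == "+":
        end = seg.end + shift
        if end - k < 0 or end > len(ref):
            return None
        return ref[end - k : end]
    start = seg.start - shift
    if start < 1 or start - 1 + k > len(ref):
        return None
    return revcomp(ref[start - 1 : start - 1 + k])


def _head_flank(ref: str, seg: Segment, strand: str, k: int, shift: int = 0) -> str | None:
    """First ``k`` bases of the oriented segment, its oriented start moved by ``shift``."""
    if strand == "+":
        start = seg.start + shift
        if start < 1 or start - 1 + k > len(ref):
            return None
        return ref[start - 1 : start - 1 + k]
    end = seg.end - shift
    if end - k < 0 or end > len(ref):
        return None
    return revcomp(ref[end - k : end])


@dataclass(frozen=True)
class AdjacencyCandidate:
    """An oriented candidate adjacency between two segment ends."""

    name: str
    donor_index: int
    donor_segment: Segment
    donor_strand: str
    acceptor_index: int
    acceptor_segment: Segment
    acceptor_strand: str
    flank_k: int
    junction_sequence: str
    donor_shift: int = 0
    acceptor_shift: int = 0
    is_reference_adjacency: bool = False

    @property
    def donor_port(self) -> tuple[int, str]:
        return (self.donor_index, "R" if self.donor_strand == "+" else "L")

    @property
    def acceptor_port(self) -> tuple[int, str]:
        return (self.acceptor_index, "L" if self.acceptor_strand == "+" else "R")

    def junction_spec(self) -> JunctionSpec:
        return JunctionSpec(
            name=self.name,
            sequence=self.junction_sequence,
            flank_k=self.flank_k,
            left_end=(self.donor_segment, "end", self.donor_strand),
            right_end=(self.acceptor_segment, "start", self.acceptor_strand),
        )


@dataclass(frozen=True)
class JunctionEvidence:
    candidate: AdjacencyCandidate
    supporting_reads: int
    is_reference_adjacency: bool

    def row(self) -> dict:
        c = self.candidate
        return {
            "candidate": c.name,
            "donor": f"{c.donor_segment}:{c.donor_strand}",
            "acceptor": f"{c.acceptor_segment}:{c.acceptor_strand}",
            "supporting_reads": self.supporting_reads,
            "reference_adjacency": self.is_reference_adjacency,
            "junction": c.junction_sequence,
        }


def _as_segments(segments) -> list[Segment]:
    out = []
    for item in segments:
        seg = item.segment if hasattr(item, "segment") else item
        out.append(seg.with_strand("+"))
    return out


def enumerate_candidates(
    segments, reference, flank_k: int = 25
) -> list[AdjacencyCandidate]:
    """All oriented end-to-start adjacencies between segments, self-joins
    included, deduplicated up to reverse complement.

    An adjacency traversed in the opposite direction is the reverse
    complement of the same physical junction, so only one representative of
    each mirror pair is kept (fold-backs are their own mirror and appear
    once).  Candidates whose 2k-mer occurs exactly in the reference, on
    either strand, are flagged as reference adjacencies.
    """
    segs = _as_segments(segments)
    if not segs:
        raise InvalidParameterError("at least one segment is required")
    ref = reference if isinstance(reference, str) else reference.sequence
    shortest = min(s.inclusive_length for s in segs)
    if flank_k < 1 or flank_k > shortest:
        raise InvalidParameterError(
            f"flank_k={flank_k} invalid for shortest segment length {shortest}"
        )
    ref_upper = ref.upper()
    out: list[AdjacencyCandidate] = []
    for (i, od), (j, oa) in product(
        product(range(len(segs)), "+-"), repeat=2
    ):
        key = (i, od, j, oa)
        mirror = (j, _flip(oa), i, _flip(od))
        if mirror < key:
            continue  # keep one representative per mirror pair
        left = _tail_flank(ref, segs[i], od, flank_k)
        right = _head_flank(ref, segs[j], oa, flank_k)
        if left is None or right is None:
            continue
        seq = (left + right).upper()
        in_ref = seq in ref_upper or revcomp(seq) in ref_upper
        out.append(
            AdjacencyCandidate(
                name=f"seg{i}{od}_to_seg{j}{oa}",
                donor_index=i,
                donor_segment=segs[i],
                donor_strand=od,
                acceptor_index=j,
                acceptor_segment=segs[j],
                acceptor_strand=oa,
                flank_k=flank_k,
                junction_sequence=seq,
                is_reference_adjacency=in_ref,
            )
        )
    return out


def _locate(pattern: str, target: str, max_edits: int) -> tuple[int, int] | None:
    """(start, end) 0-based half-open location of the best match, or None."""
    if max_edits == 0:
        p = target.find(pattern)
        return None if p == -1 else (p, p + len(pattern))
    res = edlib.align(pattern, target, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] == -1 or not res["locations"]:
        return None
    s, e = res["locations"][0]
    return (s, e + 1)


def refine_junction_flanks(
    candidate: AdjacencyCandidate,
    reference,
    reads,
    match: MatchParams = MatchParams(),
    *,
    search_window: int = 50,
    anchor_offset: int = 60,
    anchor_len: int = 50,
    max_junction_reads: int = 300,
) -> AdjacencyCandidate:
    """Move the candidate's two flank offsets to the breakpoint supported by reads.

    Junction-spanning reads are identified by an interior anchor on each side
    of the nominal boundary at a plausible spacing.  A probe 2k-mer ending at
    donor offset d matches those reads iff d does not extend past the true
    donor end; support over d is therefore a step function and the refined
    offset is the farthest offset keeping at least half the maximal support
    (ties resolve toward the unrefined, depth-called boundary by
    construction).  The acceptor offset is found symmetrically.  Candidates
    with no junction-spanning reads are returned unchanged.
    """
    if candidate.is_reference_adjacency:
        return candidate
    if anchor_offset <= search_window:
        raise InvalidParameterError("anchor_offset must exceed search_window")
    ref = reference if isinstance(reference, str) else reference.sequence
    seg_d, od = candidate.donor_segment, candidate.donor_strand
    seg_a, oa = candidate.acceptor_segment, candidate.acceptor_strand
    donor_anchor = _tail_flank(ref, seg_d, od, anchor_len, shift=-anchor_offset)
    acceptor_anchor = _head_flank(ref, seg_a, oa, anchor_len, shift=anchor_offset)
    if donor_anchor is None or acceptor_anchor is None:
        return candidate
    donor_anchor = donor_anchor.upper()
    acceptor_anchor = acceptor_anchor.upper()
    pair_gap = 2 * (anchor_offset + search_window) + anchor_len + 100

    windows: list[str] = []
    for _rid, seq in load_reads(reads):
        targets = (seq, revcomp(seq)) if match.scan_both_strands else (seq,)
        for target in targets:
            loc_d = _locate(donor_anchor, target, match.max_edits)
            if loc_d is None:
                continue
            region = target[loc_d[1] : loc_d[1] + pair_gap]
            loc_a = _locate(acceptor_anchor, region, match.max_edits)
            if loc_a is None:
                continue
            a_end = loc_d[1] + loc_a[1]
            windows.append(target[max(0, loc_d[0] - 150) : a_end + 150])
            break
        if len(windows) >= max_junction_reads:
            break
    if not windows:
        return candidate

    probe_len = 2 * candidate.flank_k
    # Probes are matched exactly even when reads are scanned approximately:
    # with an edit allowance a probe overhanging the breakpoint by up to
    # max_edits bases would still match (each overhang base costs one edit),
    # biasing the step edge.  Exact probes lower the support plateau by
    # (1 - e)^(2k) on noisy reads but keep its edge at the true breakpoint.
    probe_tolerance = 0

    def support_profile(side: str) -> dict[int, int]:
        profile = {}
        for delta in range(-search_window, search_window + 1):
            if side == "donor":
                probe = _tail_flank(ref, seg_d, od, probe_len, shift=delta)
            else:
                probe = _head_flank(ref, seg_a, oa, probe_len, shift=delta)
            if probe is None:
                continue
            probe = probe.upper()
            profile[delta] = sum(
                1 for w in windows if _matches(probe, w, probe_tolerance)
            )
        return profile

    donor_profile = support_profile("donor")
    acceptor_profile = support_profile("acceptor")
    if not donor_profile or not acceptor_profile:
        return candidate
    best_d = max(donor_profile.values())
    best_a = max(acceptor_profile.values())
    if best_d == 0 or best_a == 0:
        return candidate
    # the farthest offset that keeps the support plateau: past the true
    # breakpoint the probe leaves the circle and support collapses
    d_max = max(d for d, s in donor_profile.items() if s * 2 >= best_d)
    a_min = min(d for d, s in acceptor_profile.items() if s * 2 >= best_a)

    # Micro-homology at the breakpoint makes each one-sided step overshoot:
    # if the reference base after the donor end equals the acceptor's first
    # base, donor probes keep matching one base further while acceptor
    # probes keep matching one base earlier.  Consistent (donor, acceptor)
    # pairs lie on a diagonal along which the junction sequence is
    # invariant, so the pair is picked jointly by maximizing support of the
    # assembled 2k-mer itself, breaking ties toward the unrefined
    # (depth-called) boundary.
    homology_slack = 10
    best_key = None
    chosen = None
    for dd in range(d_max - homology_slack, d_max + 3):
        left = _tail_flank(ref, seg_d, od, candidate.flank_k, shift=dd)
        if left is None:
            continue
        for da in range(a_min - 2, a_min + homology_slack + 1):
            right = _head_flank(ref, seg_a, oa, candidate.flank_k, shift=da)
            if right is None:
                continue
            seq = (left + right).upper()
            support = sum(1 for w in windows if seq in w)
            key = (-support, abs(dd) + abs(da), abs(dd), dd, da)
            if best_key is None or key < best_key:
                best_key = key
                chosen = (dd, da, seq)
    if chosen is None or -best_key[0] == 0:
        return candidate
    donor_shift, acceptor_shift, seq = chosen
    return replace(
        candidate,
        donor_shift=donor_shift,
        acceptor_shift=acceptor_shift,
        junction_sequence=seq,
    )


def score_candidates(
    candidates: list[AdjacencyCandidate],
    reads,
    match: MatchParams = MatchParams(),
) -> list[JunctionEvidence]:
    """Supporting-read counts per candidate from a single pass over the reads."""
    scannable = [c for c in candidates if not c.is_reference_adjacency]
    report = _junctions.scan_reads(
        reads, [c.junction_spec() for c in scannable], match
    )
    evidence = []
    for c in candidates:
        support = 0 if c.is_reference_adjacency else report.counts[c.name]
        evidence.append(
            JunctionEvidence(
                candidate=c,
                supporting_reads=support,
                is_reference_adjacency=c.is_reference_adjacency,
            )
        )
    return evidence


def _evidence_table(evidence: list[JunctionEvidence]) -> list[dict]:
    return [ev.row() for ev in evidence]


def resolve_layout(
    evidence: list[JunctionEvidence],
    min_support: int = 3,
    ambiguity_factor: float = 2.0,
) -> CircleLayout:
    """Greedily accept the best-supported adjacencies into one circular layout.

    Candidates are taken in decreasing support order; one is accepted when
    both its segment ends are still unused and its support reaches
    ``min_support``.  If, at an acceptance, a conflicting candidate (sharing
    a segment end) has support within ``ambiguity_factor`` of the accepted
    one, the layout is ambiguous and resolution fails.  After acceptance the
    adjacencies must form a single Hamiltonian cycle over the segments.
    """
    if min_support < 1:
        raise InvalidParameterError("min_support must be >= 1")
    if ambiguity_factor <= 1.0:
        raise InvalidParameterError("ambiguity_factor must be > 1")
    usable = [ev for ev in evidence if not ev.is_reference_adjacency]
    order = sorted(usable, key=lambda ev: (-ev.supporting_reads, ev.candidate.name))
    n_segments = len(
        {ev.candidate.donor_index for ev in usable}
        | {ev.candidate.acceptor_index for ev in usable}
    )
    used_ports: set[tuple[int, str]] = set()
    accepted: list[JunctionEvidence] = []
    for ev in order:
        if ev.supporting_reads < min_support:
            break
        c = ev.candidate
        if c.donor_port == c.acceptor_port:  # fold-back, never placeable
            continue
        if c.donor_port in used_ports or c.acceptor_port in used_ports:
            continue
        ports = {c.donor_port, c.acceptor_port}
        for other in usable:
            if other is ev or other in accepted:
                continue
            oc = other.candidate
            if {oc.donor_port, oc.acceptor_port} & ports and (
                other.supporting_reads * ambiguity_factor >= ev.supporting_reads
            ):
                raise AmbiguousLayoutError(
                    f"competing adjacency {oc.name} "
                    f"(support {other.supporting_reads}) conflicts with "
                    f"{c.name} (support {ev.supporting_reads})",
                    evidence=_evidence_table(evidence),
                )
        used_ports |= ports
        accepted.append(ev)
        if len(accepted) == n_segments:
            break
    if len(accepted) < n_segments:
        raise IncompleteCircleError(
            f"only {len(accepted)} adjacencies accepted for "
            f"{n_segments} segments (min_support={min_support})",
            evidence=_evidence_table(evidence),
        )

    # traversal: oriented segment -> (next oriented segment, shifts)
    step: dict[tuple[int, str], tuple[int, str, int, int, Segment]] = {}
    for ev in accepted:
        c = ev.candidate
        step[(c.donor_index, c.donor_strand)] = (
            c.acceptor_index,
            c.acceptor_strand,
            c.donor_shift,
            c.acceptor_shift,
            c.acceptor_segment,
        )
        # mirror direction: the same junction read right-to-left
        step[(c.acceptor_index, _flip(c.acceptor_strand))] = (
            c.donor_index,
            _flip(c.donor_strand),
            -c.acceptor_shift,
            -c.donor_shift,
            c.donor_segment,
        )
    seg_by_index = {}
    for ev in accepted:
        seg_by_index[ev.candidate.donor_index] = ev.candidate.donor_segment
        seg_by_index[ev.candidate.acceptor_index] = ev.candidate.acceptor_segment

    start_index = min(seg_by_index)
    current = (start_index, "+")
    if current not in step:
        raise IncompleteCircleError(
            "accepted adjacencies do not traverse the first segment",
            evidence=_evidence_table(evidence),
        )
    visited: list[tuple[int, str]] = []
    head_shift: dict[int, int] = {}
    tail_shift: dict[int, int] = {}
    for _ in range(n_segments):
        visited.append(current)
        nxt_index, nxt_strand, t_shift, h_shift, _seg = step[current]
        tail_shift[current[0]] = t_shift
        head_shift[nxt_index] = h_shift
        current = (nxt_index, nxt_strand)
    if current != visited[0] or len({i for i, _ in visited}) != n_segments:
        raise IncompleteCircleError(
            "accepted adjacencies do not form a single cycle over all segments",
            evidence=_evidence_table(evidence),
        )
    elements = []
    for index, strand in visited:
        seg = seg_by_index[index]
        h = head_shift.get(index, 0)
        t = tail_shift.get(index, 0)
        if strand == "+":
            refined = Segment(seg.contig, seg.start + h, seg.end + t, "+")
        else:
            refined = Segment(seg.contig, seg.start - t, seg.end - h, "-")
        elements.append(refined)
    return CircleLayout(elements=tuple(elements))


def assemble_circle(layout: CircleLayout, reference) -> ReconstructedCircle:
    """Orientation-adjusted concatenation of the layout's segment sequences.

    The assembled length always equals the sum of the inclusive segment
    lengths, independent of orientation or later rotation.
    """
    ref = reference if isinstance(reference, str) else reference.sequence
    sequence = layout.extract_sequence(ref)
    return ReconstructedCircle(
        sequence=sequence,
        layout=layout,
        metadata={"layout": layout.layout_string()},
    )


def reconstruct(
    reference,
    duplication_calls,
    reads,
    *,
    match: MatchParams = MatchParams(),
    flank_k: int = 25,
    depth_track=None,
    refine_window: int = 2000,
    search_window: int = 50,
    min_support: int = 3,
    ambiguity_factor: float = 2.0,
) -> tuple[ReconstructedCircle, list[JunctionEvidence]]:
    """Full reconstruction driver: refine, enumerate, score, resolve, assemble."""
    from . import depthseg as _depthseg

    calls = list(duplication_calls)
    if depth_track is not None:
        calls = [
            _depthseg.refine_boundaries(c, depth_track, refine_window)
            if hasattr(c, "segment")
            else c
            for c in calls
        ]
    segments = _as_segments(calls)
    read_list = load_reads(reads)
    candidates = enumerate_candidates(segments, reference, flank_k)
    candidates = [
        refine_junction_flanks(
            c, reference, read_list, match, search_window=search_window
        )
        for c in candidates
    ]
    evidence = score_candidates(candidates, read_list, match)
    layout = resolve_layout(
        evidence, min_support=min_support, ambiguity_factor=ambiguity_factor
    )
    return assemble_circle(layout, reference), evidence
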
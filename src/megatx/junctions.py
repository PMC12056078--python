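"""Circle-specific junction sequences: construction, specificity, read scanning.

A junction is a 2k-mer (default 50 bp, k = 25 per flank) spanning an
adjacency that exists on a circular element but not on the chromosome: the
last k bases contributed by the upstream segment end followed by the first
k bases contributed by the downstream segment start, both
orientation-adjusted.  Because the adjacency is absent from the reference,
reads bearing the junction are diagnostic of the circular molecule, and
their count per gigabase of sequencing is a copy-abundance proxy.

Matching is semi-global (the junction must align end-to-end inside the
read, read ends free).  The default is exact matching; a bounded
edit-distance mode (via edlib) is provided because i.i.d. long-read errors
make an exact 50-mer hit unlikely on noisy data — with per-base error e the
chance of a clean 50-mer is (1−e)^50, about 36% at e = 2%.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .circles import CircleLayout
from .errors import InvalidParameterError, MalformedReadError
from .intervals import Segment
from .io import iter_reads
from .sequences import find_all, revcomp


@dataclass(frozen=True)
class JunctionSpec:
    """A named junction 2k-mer with the segment ends it joins."""

    name: str
    sequence: str
    flank_k: int
    left_end: tuple | None = None  # (Segment, "end"|"start", strand)
    right_end: tuple | None = None

    def __post_init__(self):
        if len(self.sequence) != 2 * self.flank_k:
            raise InvalidParameterError(
                f"junction {self.name}: |sequence|={len(self.sequence)} "
                f"!= 2*flank_k={2 * self.flank_k}"
            )


@dataclass(frozen=True)
class MatchParams:
    """How junctions are matched inside reads.

    ``max_edits`` bounds the semi-global edit distance (0 = exact, the
    procedure used on raw reads when quantifying the element); a read
    counts at most once per junction regardless of how often it matches.
    """

    max_edits: int = 0
    scan_both_strands: bool = True

    def __post_init__(self):
        if self.max_edits < 0:
            raise InvalidParameterError("max_edits must be >= 0")


NOISY_PRESET = MatchParams(max_edits=3)


@dataclass
class JunctionHitReport:
    counts: dict[str, int]
    hit_read_ids: dict[str, list[str]]
    total_bases_scanned: int
    n_reads: int

    @property
    def defined(self) -> bool:
        """False when no bases were scanned (reads-per-Gb is then undefined)."""
        return self.total_bases_scanned > 0

    def reads_per_gb(self, name: str) -> float | None:
        if not self.defined:
            return None
        return self.counts[name] / (self.total_bases_scanned / 1e9)

    def to_rows(self, min_reads: int = 1) -> list[dict]:
        return [
            {
                "junction": name,
                "read_count": count,
                "total_bases": self.total_bases_scanned,
                "reads_per_gb": self.reads_per_gb(name),
                "presence": count >= min_reads,
            }
            for name, count in self.counts.items()
        ]


def _reference_sequence(reference) -> str:
    return reference if isinstance(reference, str) else reference.sequence


def build_junctions(
    layout: CircleLayout, reference, flank_k: int = 25
) -> list[JunctionSpec]:
    """One junction per adjacency of the circular layout (n segments → n).

    For the two-segment forward-forward case this yields
    junction A = last k of segment 1 + first k of segment 2 and
    junction B = last k of segment 2 + first k of segment 1.
    """
    ref = _reference_sequence(reference)
    if flank_k < 1:
        raise InvalidParameterError("flank_k must be >= 1")
    for seg in layout.elements:
        if seg.inclusive_length < flank_k:
            raise InvalidParameterError(
                f"flank_k={flank_k} exceeds segment length {seg.inclusive_length}"
            )
    specs = []
    for i, (left, right) in enumerate(layout.adjacencies(), start=1):
        left_seq = left.oriented_sequence(ref)
        right_seq = right.oriented_sequence(ref)
        specs.append(
            JunctionSpec(
                name=f"junction_{i}",
                sequence=left_seq[-flank_k:] + right_seq[:flank_k],
                flank_k=flank_k,
                left_end=(left, "end", left.strand),
                right_end=(right, "start", right.strand),
            )
        )
    return specs


@dataclass(frozen=True)
class SpecificityResult:
    is_specific: bool
    occurrences: tuple[tuple[int, str], ...]  # (1-based position, strand)


def check_specificity(
    junction: JunctionSpec, reference, circular: bool = False
) -> SpecificityResult:
    """True iff neither the junction nor its reverse complement occurs in the
    reference (including the wrap-around window when the reference is
    circular)."""
    ref = _reference_sequence(reference).upper()
    query = junction.sequence.upper()
    L = len(query)
    hits: list[tuple[int, str]] = []
    for strand, pattern in (("+", query), ("-", revcomp(query))):
        hits.extend((p + 1, strand) for p in find_all(pattern, ref))
        if circular and L > 1:
            wrap = ref[-(L - 1) :] + ref[: L - 1]
            offset = len(ref) - (L - 1)
            hits.extend((offset + p + 1, strand) for p in find_all(pattern, wrap))
    return SpecificityResult(is_specific=not hits, occurrences=tuple(hits))


def _matches(pattern: str, read: str, max_edits: int) -> bool:
    if max_edits == 0:
        return pattern in read
    result = edlib.align(pattern, read, mode="HW", task="distance", k=max_edits)
    return result["editDistance"] != -1


def scan_reads(
    reads, junctions: list[JunctionSpec], params: MatchParams = MatchParams()
) -> JunctionHitReport:
    """Count reads bearing each junction (≤ 1 count per junction per read).

    ``reads`` may be a FASTA/FASTQ path (optionally gzipped) or an in-memory
    collection.  ``total_bases_scanned`` sums read lengths as given in the
    input (no trimming); reads-per-Gb divides by that total in gigabases and
    is flagged undefined (not NaN) for an empty input.
    """
    for j in junctions:
        if len(j.sequence) < 2 * params.max_edits + 1:
            raise InvalidParameterError(
                f"junction {j.name} shorter than 2*max_edits+1"
            )
    patterns = []
    for j in junctions:
        seq = j.sequence.upper()
        strands = [seq, revcomp(seq)] if params.scan_both_strands else [seq]
        patterns.append((j.name, strands))
    counts = {j.name: 0 for j in junctions}
    ids: dict[str, list[str]] = {j.name: [] for j in junctions}
    total = 0
    n_reads = 0
    for rid, seq in iter_reads(reads):
        if not seq:
            raise MalformedReadError(f"empty read {rid}", record_index=n_reads)
        n_reads += 1
        total += len(seq)
        for name, strands in patterns:
            if any(_matches(p, seq, params.max_edits) for p in strands):
                counts[name] += 1
                ids[name].append(rid)
    return JunctionHitReport(
        counts=counts, hit_read_ids=ids, total_bases_scanned=total, n_reads=n_reads
    )


def call_presence(report: JunctionHitReport, min_reads: int = 1) -> dict[str, bool]:
    """Presence flag per junction: read_count >= min_reads."""
    if min_reads < 1:
        raise InvalidParameterError("min_reads must be >= 1")
    return {name: count >= min_reads for name, count in report.counts.items()}
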
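"""Genomic intervals with the two length conventions used in reports.

Coordinates are 1-based and inclusive throughout the package, matching how
bacterial genome coordinates are conventionally printed.  Two lengths are
attached to every segment:

* ``inclusive_length`` = end − start + 1 — the number of bases, which is what
  sums to the length of an assembled circular element;
* ``span`` = end − start — the coordinate difference, which is how rearranged
  regions are often quoted in genome-resequencing reports.

Both are carried side by side (and labelled) because mixing them up shifts
every length accounting by one per segment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import InvalidIntervalError
from .sequences import revcomp


@dataclass(frozen=True)
class Segment:
    """A 1-based inclusive genomic interval with orientation."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise InvalidIntervalError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise InvalidIntervalError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def inclusive_length(self) -> int:
        return self.end - self.start + 1

    @property
    def span(self) -> int:
        """end − start, the coordinate-difference convention."""
        return self.end - self.start

    def overlaps(self, other: "Segment") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains_position(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def forward_sequence(self, contig_sequence: str) -> str:
        """Bases of the interval on the forward strand."""
        if self.end > len(contig_sequence):
            raise InvalidIntervalError(
                f"{self.contig}:{self.start}-{self.end} exceeds contig "
                f"length {len(contig_sequence)}"
            )
        return contig_sequence[self.start - 1 : self.end]

    def oriented_sequence(self, contig_sequence: str) -> str:
        """Bases as read along the segment's own orientation."""
        seq = self.forward_sequence(contig_sequence)
        return seq if self.strand == "+" else revcomp(seq)

    def with_strand(self, strand: str) -> "Segment":
        return replace(self, strand=strand)

    def __str__(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}({self.strand})"


def gap_between(left: Segment, right: Segment) -> dict:
    """Distance between two ordered segments under the common conventions.

    Returns the coordinate difference ``right.start − left.end``, the inclusive
    count of bases from ``left.end`` through ``right.start``, and the number of
    bases strictly between the two segments.  Reports print all three, labelled,
    because published "separated by" figures use either of the first two.
    """
    if right.start <= left.end:
        raise InvalidIntervalError("segments are not ordered/disjoint")
    return {
        "start_minus_end": right.start - left.end,
        "end_through_start_inclusive": right.start - left.end + 1,
        "intervening_bases": right.start - left.end - 1,
    }
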
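"""Circular-element containers: layouts of oriented segments and assembled circles."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidIntervalError, InvalidParameterError
from .intervals import Segment


@dataclass(frozen=True)
class CircleLayout:
    """An ordered, oriented list of segments whose ends are joined cyclically.

    Element ``i``'s oriented end is adjacent to element ``i+1``'s oriented
    start; the last element wraps to the first.  Each segment appears once,
    so each segment end participates in exactly one adjacency.
    """

    elements: tuple[Segment, ...]

    def __post_init__(self):
        if not self.elements:
            raise InvalidParameterError("a circle layout needs at least one segment")

    @property
    def n_segments(self) -> int:
        return len(self.elements)

    @property
    def total_inclusive_length(self) -> int:
        return sum(seg.inclusive_length for seg in self.elements)

    def adjacencies(self) -> list[tuple[Segment, Segment]]:
        """Cyclic (end-of-left, start-of-right) pairs, one per junction."""
        n = len(self.elements)
        return [(self.elements[i], self.elements[(i + 1) % n]) for i in range(n)]

    def layout_string(self) -> str:
        return ";".join(
            f"{seg.contig}:{seg.start}-{seg.end}:{seg.strand}" for seg in self.elements
        )

    def extract_sequence(self, reference_sequence: str) -> str:
        return "".join(seg.oriented_sequence(reference_sequence) for seg in self.elements)


@dataclass(frozen=True)
class CircularElement:
    """A circular DNA molecule with a known layout (e.g. a simulated truth circle)."""

    name: str
    sequence: str
    layout: CircleLayout

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReconstructedCircle:
    """A circle assembled from a resolved layout against a reference."""

    sequence: str
    layout: CircleLayout
    rotation_anchor: int = 1  # 1-based position of the original origin
    name: str = "circle"
    metadata: dict = field(default_factory=dict, compare=False)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fasta_header(self) -> str:
        return f"{self.name} length={self.length} layout={self.layout.layout_string()}"


def rotate_to_anchor(circle: ReconstructedCircle, anchor: int) -> ReconstructedCircle:
    """Rotate a circle so that 1-based position ``anchor`` becomes position 1.

    Rotating by the circle length (anchor = length + 1 is out of range; anchor
    = 1 is the identity) leaves the sequence unchanged, and rotations compose
    additively modulo the length.
    """
    if not 1 <= anchor <= circle.length:
        raise InvalidParameterError(
            f"anchor {anchor} outside circle of length {circle.length}"
        )
    seq = circle.sequence[anchor - 1 :] + circle.sequence[: anchor - 1]
    # Track the cumulative rotation so successive calls compose.
    origin = ((circle.rotation_anchor - 1) + (anchor - 1)) % circle.length + 1
    return ReconstructedCircle(
        sequence=seq,
        layout=circle.layout,
        rotation_anchor=origin,
        name=circle.name,
        metadata=dict(circle.metadata),
    )


def circular_equal(a: str, b: str, *, allow_revcomp: bool = False) -> bool:
    """Whether two sequences are identical as circular molecules.

    Two strings of equal length are rotations of each other iff one occurs
    in the doubled other.  The breakpoint of a circular junction is only
    defined up to any micro-homology between its flanks, so reconstructed
    circles are compared rotation-invariantly.
    """
    if len(a) != len(b):
        return False
    if a in b + b:
        return True
    if allow_revcomp:
        from .sequences import revcomp

        return revcomp(a) in b + b
    return False


def validate_layout_on_reference(layout: CircleLayout, reference_length: int) -> None:
    for seg in layout.elements:
        if seg.end > reference_length:
            raise InvalidIntervalError(
                f"layout segment {seg} exceeds reference length {reference_length}"
            )
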
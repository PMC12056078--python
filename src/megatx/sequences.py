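"""Small DNA string helpers used throughout the package."""

from __future__ import annotations

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def find_all(pattern: str, text: str) -> list[int]:
    """All 0-based start positions of exact occurrences of ``pattern`` in ``text``."""
    positions = []
    i = text.find(pattern)
    while i != -1:
        positions.append(i)
        i = text.find(pattern, i + 1)
    return positions


def validate_dna(seq: str, *, allow_n: bool = False) -> None:
    allowed = DNA_ALPHABET | ({"N"} if allow_n else set())
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
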
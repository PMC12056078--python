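"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written for clarity over speed and shares no code with
the package internals it checks.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def semiglobal_edit_distance(pattern: str, text: str) -> int:
    """Minimum edit distance of ``pattern`` against any substring of ``text``.

    Full dynamic program: the first row is zero (free start anywhere in the
    text) and the answer is the minimum of the last row (free end).
    """
    m, n = len(pattern), len(text)
    prev = np.zeros(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        cur = np.empty(n + 1, dtype=np.int32)
        cur[0] = i
        p = pattern[i - 1]
        sub = prev[:-1] + np.frombuffer(
            bytes(0 if p == c else 1 for c in text), dtype=np.uint8
        )
        dele = prev[1:] + 1
        cur[1:] = np.minimum(sub, dele)
        # insertion needs a left-to-right pass
        for j in range(1, n + 1):
            if cur[j - 1] + 1 < cur[j]:
                cur[j] = cur[j - 1] + 1
        prev = cur
    return int(prev.min())


def brute_force_segment_calls(ratios, dup_threshold, del_threshold, max_gap_bins):
    """Maximal qualifying bin runs with gap merging, as an explicit scan.

    Returns ``(kind, first_bin, last_bin)`` triples before any minimum-length
    filtering; gaps of at most ``max_gap_bins`` neutral bins are bridged
    unless a bin inside the gap qualifies for the opposite kind.
    """
    n = len(ratios)

    def qualifies(i, kind):
        return ratios[i] >= dup_threshold if kind == "dup" else ratios[i] <= del_threshold

    out = []
    for kind, other in (("dup", "del"), ("del", "dup")):
        runs = []
        i = 0
        while i < n:
            if not qualifies(i, kind):
                i += 1
                continue
            start = i
            end = i
            j = i + 1
            gap = 0
            while j < n:
                if qualifies(j, kind):
                    end = j
                    gap = 0
                elif qualifies(j, other):
                    break
                else:
                    gap += 1
                    if gap > max_gap_bins:
                        break
                j += 1
            runs.append((kind, start, end))
            i = end + 1
        out.extend(runs)
    return out


def brute_force_adjacency_set(segment_sequences: list[str], flank_k: int) -> set[str]:
    """Canonical junction 2k-mers of every oriented end-to-start adjacency.

    Each physical adjacency is represented by the lexicographic minimum of
    its sequence and reverse complement, which is exactly the
    mirror-deduplication the enumerator performs.
    """
    oriented = []
    for seq in segment_sequences:
        oriented.append(seq)
        oriented.append(revcomp(seq))
    out = set()
    for donor in oriented:
        for acceptor in oriented:
            j = donor[-flank_k:] + acceptor[:flank_k]
            out.add(min(j, revcomp(j)))
    return out


def mutate_with_edits(rng: np.random.Generator, seq: str, n_edits: int) -> str:
    """Apply exactly ``n_edits`` random single-base edits, one at a time."""
    bases = "ACGT"
    s = list(seq)
    for _ in range(n_edits):
        op = rng.integers(0, 3)
        pos = int(rng.integers(0, len(s)))
        if op == 0:  # substitution (to a different base)
            choices = [b for b in bases if b != s[pos]]
            s[pos] = choices[int(rng.integers(0, 3))]
        elif op == 1 and len(s) > 1:  # deletion
            del s[pos]
        else:  # insertion
            s.insert(pos, bases[int(rng.integers(0, 4))])
    return "".join(s)
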
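"""Synthetic genomes, circular elements, depth tracks and long reads.

This module emulates the data underlying the discovery of a CO-dependent
circular megatransposon in an acetogen: a bacterial chromosome carrying two
duplicated regions that, read head-to-tail, form one circular
extrachromosomal element.  Everything downstream (depth segmentation,
junction scanning, circle reconstruction) is exercised against scenarios
generated here, with full knowledge of the truth:

* ``generate_genome`` — an i.i.d. random chromosome at a target GC content;
* ``build_scenario`` — the circular element composed of two forward-forward
  chromosomal segments skipping the intervening gap, plus its two
  circle-specific junctions;
* ``simulate_depth_track`` — per-base Poisson coverage with copy-ratio
  events (a duplicated region at ratio ~2.2, a deletion at ratio 0), the
  short-read coverage signal without needing an aligner;
* ``simulate_long_reads`` — noisy long reads with truncated-lognormal
  lengths drawn from a weighted mixture of molecules (chromosome and
  circle), with per-read truth records.

All randomness flows through a single ``numpy`` generator per call, seeded
by a required argument: identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import junctions as _junctions
from .circles import CircleLayout, CircularElement
from .depthseg import DepthTrack
from .errors import InvalidIntervalError, InvalidParameterError
from .intervals import Segment
from .sequences import gc_fraction as _gc_fraction
from .sequences import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# uint8 base code -> 0..3 index (A,C,G,T)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[_b] = _i


@dataclass(frozen=True)
class GenomeModel:
    """A named chromosome sequence over the ACGT alphabet."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        return _gc_fraction(self.sequence)


@dataclass(frozen=True)
class ReadSimParams:
    """Long-read simulation parameters.

    Lengths are drawn from a lognormal truncated to ``[min_length,
    max_length]``.  The default ``median_length`` of 5,697 bases matches the
    raw-read N50 scale of a PromethION run on bacterial gDNA; ``max_length``
    caps at 50 kb.  Errors are i.i.d. per base: a base is first deleted with
    probability ``deletion_rate``, surviving bases are substituted with
    ``substitution_rate``, and a random base is inserted after a base with
    ``insertion_rate``.  Defaults (2% / 1.5% / 2%) give a ~94-95% identity
    read set, enough to make exact 50-mer matching insensitive and
    approximate matching necessary.
    """

    total_bases: int
    seed: int
    median_length: float = 5697.0
    sigma_log: float = 0.6
    min_length: int = 200
    max_length: int = 50_000
    substitution_rate: float = 0.02
    insertion_rate: float = 0.015
    deletion_rate: float = 0.02

    def __post_init__(self):
        if self.total_bases <= 0:
            raise InvalidParameterError("total_bases must be positive")
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.3:
                raise InvalidParameterError(f"{name}={rate} outside [0, 0.3]")
        if not 0 < self.min_length <= self.max_length:
            raise InvalidParameterError("need 0 < min_length <= max_length")

    @property
    def mean_log(self) -> float:
        return math.log(self.median_length)

    def error_free(self) -> bool:
        return (
            self.substitution_rate == 0
            and self.insertion_rate == 0
            and self.deletion_rate == 0
        )


@dataclass(frozen=True)
class ReadSource:
    """A molecule reads can be drawn from, with a relative abundance weight.

    A source is selected with probability proportional to
    ``weight * len(sequence)``, i.e. ``weight`` plays the role of per-cell
    copy number of the molecule.
    """

    name: str
    sequence: str
    circular: bool = False
    weight: float = 1.0


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    source: str
    start: int  # 1-based leftmost template position on the forward source
    strand: str
    template_length: int


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    truth: ReadTruth

    @property
    def quality(self) -> str:
        return "I" * len(self.sequence)  # dummy; never used downstream


@dataclass
class ReadSetTruth:
    reads: list[ReadTruth]
    total_template_bases: int
    sources: dict[str, int]  # template bases per source


@dataclass
class TruthSet:
    """Ground truth of a simulated scenario."""

    segments: list[tuple[Segment, float]] = field(default_factory=list)
    junctions: list = field(default_factory=list)
    circle: CircularElement | None = None
    read_truth: ReadSetTruth | None = None


def generate_genome(
    length: int, gc_fraction: float, seed: int, name: str = "sim_chromosome"
) -> GenomeModel:
    """An i.i.d. random chromosome with expected GC content ``gc_fraction``."""
    if length < 1000:
        raise InvalidParameterError(f"genome length must be >= 1000, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise InvalidParameterError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(_BASES, size=length, p=[at, gc, gc, at])
    return GenomeModel(name=name, sequence=codes.tobytes().decode("ascii"))


def build_scenario(
    genome: GenomeModel, dup1: Segment, dup2: Segment, flank_k: int = 25
) -> tuple[CircularElement, TruthSet]:
    """Compose the circular element from two forward chromosomal segments.

    The circle reads dup1 then dup2 (both forward), skipping the gap between
    them; its two adjacencies — end-of-dup1 to start-of-dup2 and end-of-dup2
    back to start-of-dup1 — exist only on the circle, never on the
    chromosome, and are returned as truth junctions.
    """
    for seg in (dup1, dup2):
        if seg.end > genome.length:
            raise InvalidIntervalError(f"{seg} exceeds genome length {genome.length}")
    if dup1.overlaps(dup2) or dup2.start <= dup1.end:
        raise InvalidIntervalError(
            f"duplications must be disjoint and ordered: {dup1} vs {dup2}"
        )
    layout = CircleLayout(elements=(dup1.with_strand("+"), dup2.with_strand("+")))
    sequence = layout.extract_sequence(genome.sequence)
    circle = CircularElement(name="sim_circle", sequence=sequence, layout=layout)
    truth_junctions = _junctions.build_junctions(layout, genome, flank_k=flank_k)
    truth = TruthSet(
        segments=[(dup1, 2.2), (dup2, 2.2)],
        junctions=truth_junctions,
        circle=circle,
    )
    return circle, truth


def simulate_depth_track(
    genome: GenomeModel,
    events: list[tuple[Segment, float]],
    mean_depth: float,
    seed: int,
) -> DepthTrack:
    """Per-base Poisson coverage with local copy-ratio events.

    Depth at base i is Poisson(mean_depth * ratio(i)); ratio is 1 outside
    events, the event's copy ratio inside (0 encodes a deletion).
    """
    if mean_depth <= 0:
        raise InvalidParameterError("mean_depth must be positive")
    ratio = np.ones(genome.length)
    seen: list[Segment] = []
    for seg, r in events:
        if r < 0:
            raise InvalidParameterError(f"copy_ratio must be >= 0, got {r}")
        if seg.end > genome.length:
            raise InvalidIntervalError(f"event {seg} exceeds genome length")
        for prev in seen:
            if prev.overlaps(seg):
                raise InvalidParameterError(f"overlapping events: {prev} and {seg}")
        seen.append(seg)
        ratio[seg.start - 1 : seg.end] = r
    rng = np.random.default_rng(seed)
    depth = rng.poisson(mean_depth * ratio).astype(float)
    return DepthTrack(contig=genome.name, depth=depth)


def _mutate(codes: np.ndarray, rng: np.random.Generator, params: ReadSimParams) -> np.ndarray:
    """Apply i.i.d. per-base deletion, substitution and insertion errors."""
    if params.error_free():
        return codes
    if params.deletion_rate > 0:
        codes = codes[rng.random(codes.size) >= params.deletion_rate]
    codes = codes.copy()
    if params.substitution_rate > 0 and codes.size:
        sub = rng.random(codes.size) < params.substitution_rate
        n_sub = int(sub.sum())
        if n_sub:
            idx = _BASE_INDEX[codes[sub]].astype(np.int64)
            codes[sub] = _BASES[(idx + rng.integers(1, 4, n_sub)) % 4]
    if params.insertion_rate > 0 and codes.size:
        ins = rng.random(codes.size) < params.insertion_rate
        n_ins = int(ins.sum())
        if n_ins:
            reps = ins.astype(np.int64) + 1
            out = np.repeat(codes, reps)
            # the inserted copy sits right after its template base
            out[(np.cumsum(reps) - 1)[ins]] = _BASES[rng.integers(0, 4, n_ins)]
            codes = out
    return codes


def simulate_long_reads(
    sources: list[ReadSource], params: ReadSimParams
) -> tuple[list[SimulatedRead], ReadSetTruth]:
    """Draw long reads from a weighted mixture of linear/circular molecules.

    Start positions are uniform on each source; reads wrap around circular
    sources and are truncated at the ends of linear ones.  Template bases are
    accumulated until ``params.total_bases`` is reached (the final read may
    overshoot, so the total is within one read of the target).
    """
    if not sources:
        raise InvalidParameterError("at least one read source is required")
    if any(s.weight < 0 for s in sources):
        raise InvalidParameterError("source weights must be >= 0")
    raw = np.array([s.weight * len(s.sequence) for s in sources], dtype=float)
    if raw.sum() <= 0:
        raise InvalidParameterError("at least one source needs a positive weight")
    probs = raw / raw.sum()
    rng = np.random.default_rng(params.seed)

    reads: list[SimulatedRead] = []
    truths: list[ReadTruth] = []
    per_source = {s.name: 0 for s in sources}
    total = 0
    read_no = 0
    while total < params.total_bases:
        src = sources[int(rng.choice(len(sources), p=probs))]
        length = 0
        while True:  # rejection-sample the truncated lognormal
            draw = rng.lognormal(params.mean_log, params.sigma_log)
            if params.min_length <= draw <= params.max_length:
                length = int(round(draw))
                break
        mol_len = len(src.sequence)
        length = min(length, mol_len)
        start0 = int(rng.integers(0, mol_len))
        if src.circular:
            stop = start0 + length
            template = (
                src.sequence[start0:stop]
                if stop <= mol_len
                else src.sequence[start0:] + src.sequence[: stop - mol_len]
            )
        else:
            template = src.sequence[start0 : start0 + length]
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if strand == "-":
            template = revcomp(template)
        codes = np.frombuffer(template.encode("ascii"), dtype=np.uint8)
        seq = _mutate(codes, rng, params).tobytes().decode("ascii")
        read_no += 1
        rid = f"read_{read_no:06d}_{src.name}"
        truth = ReadTruth(
            read_id=rid,
            source=src.name,
            start=start0 + 1,
            strand=strand,
            template_length=len(template),
        )
        reads.append(SimulatedRead(read_id=rid, sequence=seq, truth=truth))
        truths.append(truth)
        per_source[src.name] += len(template)
        total += len(template)
    return reads, ReadSetTruth(
        reads=truths, total_template_bases=total, sources=per_source
    )


def simulate_short_reads(
    genome: GenomeModel,
    n_reads: int,
    read_length: int,
    seed: int,
    substitution_rate: float = 0.0,
) -> list[SimulatedRead]:
    """A minimal single-end short-read emitter for users who want to run a
    real aligner; no pipeline stage depends on it."""
    if n_reads <= 0 or read_length <= 0:
        raise InvalidParameterError("n_reads and read_length must be positive")
    rng = np.random.default_rng(seed)
    reads = []
    max_start = genome.length - read_length
    for i in range(n_reads):
        start0 = int(rng.integers(0, max_start + 1))
        template = genome.sequence[start0 : start0 + read_length]
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if strand == "-":
            template = revcomp(template)
        if substitution_rate > 0:
            codes = np.frombuffer(template.encode("ascii"), dtype=np.uint8).copy()
            sub = rng.random(codes.size) < substitution_rate
            n_sub = int(sub.sum())
            if n_sub:
                idx = _BASE_INDEX[codes[sub]].astype(np.int64)
                codes[sub] = _BASES[(idx + rng.integers(1, 4, n_sub)) % 4]
            template = codes.tobytes().decode("ascii")
        truth = ReadTruth(
            read_id=f"sr_{i:06d}",
            source=genome.name,
            start=start0 + 1,
            strand=strand,
            template_length=read_length,
        )
        reads.append(SimulatedRead(read_id=truth.read_id, sequence=template, truth=truth))
    return reads
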
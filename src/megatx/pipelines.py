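"""End-to-end drivers over the synthetic case study.

The default scenario mirrors the geometry of the real discovery, scaled to
desk size: a 150 kb chromosome carrying two forward duplications (17.2 kb
and 11.8 kb, separated by a 6.1 kb gap) whose head-to-tail join forms a
29 kb circular element; short-read coverage at ~2.2x inside the
duplications; long reads drawn from a chromosome + circle mixture.  The
duplication boundaries deliberately do not align to the 1 kb analysis bins,
so recovering them exercises boundary refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import circlerec, depthseg, junctions, simdata
from .circles import CircularElement, circular_equal
from .intervals import Segment

GENOME_LENGTH = 150_000
GC_FRACTION = 0.35
DUP1 = (40_234, 57_417)
DUP2 = (63_561, 75_377)
MEAN_DEPTH = 150.0
COPY_RATIO = 2.2
TOTAL_READ_BASES = 1_500_000
CIRCLE_WEIGHT = 15.0


@dataclass
class Scenario:
    genome: simdata.GenomeModel
    dup1: Segment
    dup2: Segment
    circle: CircularElement
    truth: simdata.TruthSet
    track: depthseg.DepthTrack


def default_scenario(
    seed: int,
    *,
    genome_length: int = GENOME_LENGTH,
    dup1: tuple[int, int] = DUP1,
    dup2: tuple[int, int] = DUP2,
    mean_depth: float = MEAN_DEPTH,
    copy_ratio: float = COPY_RATIO,
) -> Scenario:
    genome = simdata.generate_genome(genome_length, GC_FRACTION, seed)
    seg1 = Segment(genome.name, *dup1)
    seg2 = Segment(genome.name, *dup2)
    circle, truth = simdata.build_scenario(genome, seg1, seg2)
    track = simdata.simulate_depth_track(
        genome, [(seg1, copy_ratio), (seg2, copy_ratio)], mean_depth, seed + 1_000_000
    )
    return Scenario(
        genome=genome, dup1=seg1, dup2=seg2, circle=circle, truth=truth, track=track
    )


def scenario_reads(
    scenario: Scenario,
    seed: int,
    *,
    total_bases: int = TOTAL_READ_BASES,
    circle_weight: float = CIRCLE_WEIGHT,
    substitution_rate: float = 0.0,
    insertion_rate: float = 0.0,
    deletion_rate: float = 0.0,
) -> tuple[list[simdata.SimulatedRead], simdata.ReadSetTruth]:
    params = simdata.ReadSimParams(
        total_bases=total_bases,
        seed=seed + 2_000_000,
        substitution_rate=substitution_rate,
        insertion_rate=insertion_rate,
        deletion_rate=deletion_rate,
    )
    sources = [
        simdata.ReadSource(scenario.genome.name, scenario.genome.sequence,
                           circular=False, weight=1.0),
        simdata.ReadSource(scenario.circle.name, scenario.circle.sequence,
                           circular=True, weight=circle_weight),
    ]
    return simdata.simulate_long_reads(sources, params)


def run_end_to_end(
    seed: int,
    *,
    substitution_rate: float = 0.0,
    max_edits: int = 0,
    total_bases: int = TOTAL_READ_BASES,
    circle_weight: float = CIRCLE_WEIGHT,
) -> dict:
    """Simulate, depth-call, enumerate, score, resolve and assemble one scenario.

    Returns the recovery summary: whether the assembled circle matches the
    truth byte-for-byte, whether it matches as a circular molecule (the
    breakpoint is only defined up to junction micro-homology), and the
    evidence table.
    """
    scenario = default_scenario(seed)
    reads, _ = scenario_reads(
        scenario, seed,
        total_bases=total_bases,
        circle_weight=circle_weight,
        substitution_rate=substitution_rate,
    )
    binned = depthseg.bin_and_normalize(scenario.track)
    calls = [
        c for c in depthseg.call_segments(binned) if c.kind == "duplication"
    ]
    circle, evidence = circlerec.reconstruct(
        scenario.genome.sequence,
        calls,
        reads,
        depth_track=scenario.track,
        match=junctions.MatchParams(max_edits=max_edits),
    )
    return {
        "scenario": scenario,
        "n_duplication_calls": len(calls),
        "reconstructed": circle,
        "evidence": evidence,
        "byte_exact": circle.sequence == scenario.circle.sequence,
        "circular_exact": circular_equal(circle.sequence, scenario.circle.sequence),
        "length_match": circle.length == scenario.circle.length,
    }
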
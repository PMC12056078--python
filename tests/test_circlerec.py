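"""Circle reconstruction: candidate enumeration, resolution, assembly, rotation."""

import pytest
from hypothesis import given, strategies as st

from megatx import circlerec, junctions, pipelines, simdata
from megatx.circles import CircleLayout, ReconstructedCircle, circular_equal, rotate_to_anchor
from megatx.errors import (
    AmbiguousLayoutError,
    IncompleteCircleError,
    InvalidParameterError,
)
from megatx.intervals import Segment
from megatx.junctions import MatchParams

from oracles import brute_force_adjacency_set
from oracles import revcomp as oracle_revcomp


@pytest.fixture(scope="module")
def genome_5k():
    return simdata.generate_genome(5000, 0.45, seed=9)


def _canonical(seq):
    return min(seq, oracle_revcomp(seq))


class TestEnumerateCandidates:
    def test_two_segments_match_brute_force_enumeration(self, genome_5k):
        segs = [Segment(genome_5k.name, 501, 1500), Segment(genome_5k.name, 2501, 3200)]
        cands = circlerec.enumerate_candidates(segs, genome_5k, flank_k=25)
        got = {_canonical(c.junction_sequence) for c in cands}
        expected = brute_force_adjacency_set(
            [s.forward_sequence(genome_5k.sequence) for s in segs], 25
        )
        assert got == expected
        assert len(cands) == len(got)  # one representative per mirror class

    def test_single_segment_candidates(self, genome_5k):
        segs = [Segment(genome_5k.name, 501, 1500)]
        cands = circlerec.enumerate_candidates(segs, genome_5k, flank_k=25)
        got = {_canonical(c.junction_sequence) for c in cands}
        expected = brute_force_adjacency_set(
            [segs[0].forward_sequence(genome_5k.sequence)], 25
        )
        # head-to-tail circle plus the two distinct fold-backs
        assert got == expected
        assert len(got) == 3

    def test_reference_collinear_adjacency_flagged(self, genome_5k):
        segs = [Segment(genome_5k.name, 501, 1500), Segment(genome_5k.name, 1501, 2500)]
        cands = circlerec.enumerate_candidates(segs, genome_5k, flank_k=25)
        collinear = [
            c for c in cands
            if (c.donor_index, c.donor_strand, c.acceptor_index, c.acceptor_strand)
            == (0, "+", 1, "+")
        ]
        assert collinear and collinear[0].is_reference_adjacency

    def test_flank_wider_than_shortest_segment_rejected(self, genome_5k):
        segs = [Segment(genome_5k.name, 501, 520), Segment(genome_5k.name, 1001, 2000)]
        with pytest.raises(InvalidParameterError):
            circlerec.enumerate_candidates(segs, genome_5k, flank_k=25)


class TestScoreCandidates:
    def test_chromosome_only_reads_score_zero(self, scenario, chromosome_only_reads):
        reads, _ = chromosome_only_reads
        cands = circlerec.enumerate_candidates(
            [scenario.dup1, scenario.dup2], scenario.genome
        )
        evidence = circlerec.score_candidates(cands, reads, MatchParams())
        assert all(ev.supporting_reads == 0 for ev in evidence)

    def test_truth_adjacencies_have_top_support(self, scenario, error_free_reads):
        reads, _ = error_free_reads
        cands = circlerec.enumerate_candidates(
            [scenario.dup1, scenario.dup2], scenario.genome
        )
        evidence = sorted(
            circlerec.score_candidates(cands, reads, MatchParams()),
            key=lambda ev: -ev.supporting_reads,
        )
        truth_seqs = {_canonical(j.sequence) for j in scenario.truth.junctions}
        top_two = {_canonical(ev.candidate.junction_sequence) for ev in evidence[:2]}
        assert top_two == truth_seqs
        assert evidence[1].supporting_reads >= 3
        assert evidence[2].supporting_reads == 0

    def test_duplicated_read_file_doubles_support(self, scenario, error_free_reads):
        reads, _ = error_free_reads
        subset = [(r.read_id, r.sequence) for r in reads[:150]]
        cands = circlerec.enumerate_candidates(
            [scenario.dup1, scenario.dup2], scenario.genome
        )
        once = circlerec.score_candidates(cands, subset, MatchParams())
        twice = circlerec.score_candidates(cands, subset * 2, MatchParams())
        for a, b in zip(once, twice):
            assert b.supporting_reads == 2 * a.supporting_reads


class TestResolveLayout:
    def _evidence(self, scenario, supports):
        cands = circlerec.enumerate_candidates(
            [scenario.dup1, scenario.dup2], scenario.genome
        )
        return [
            circlerec.JunctionEvidence(
                candidate=c,
                supporting_reads=supports.get(
                    (c.donor_index, c.donor_strand, c.acceptor_index, c.acceptor_strand),
                    0,
                ),
                is_reference_adjacency=c.is_reference_adjacency,
            )
            for c in cands
        ]

    def test_two_supported_truth_junctions_resolve_forward_cycle(self, scenario):
        # junction A: dup1+ -> dup2+; junction B appears as its mirror 0- -> 1-
        evidence = self._evidence(
            scenario, {(0, "+", 1, "+"): 40, (0, "-", 1, "-"): 37}
        )
        layout = circlerec.resolve_layout(evidence)
        assert [(s.start, s.end, s.strand) for s in layout.elements] == [
            (scenario.dup1.start, scenario.dup1.end, "+"),
            (scenario.dup2.start, scenario.dup2.end, "+"),
        ]

    def test_competing_support_raises_ambiguity(self, scenario):
        evidence = self._evidence(
            scenario,
            {(0, "+", 1, "+"): 40, (0, "-", 1, "-"): 37, (0, "+", 1, "-"): 25},
        )
        with pytest.raises(AmbiguousLayoutError) as err:
            circlerec.resolve_layout(evidence, ambiguity_factor=2.0)
        assert err.value.evidence  # evidence table attached

    def test_single_supported_junction_is_incomplete(self, scenario):
        evidence = self._evidence(scenario, {(0, "+", 1, "+"): 40})
        with pytest.raises(IncompleteCircleError):
            circlerec.resolve_layout(evidence)

    def test_min_support_gate(self, scenario):
        evidence = self._evidence(
            scenario, {(0, "+", 1, "+"): 2, (0, "-", 1, "-"): 2}
        )
        with pytest.raises(IncompleteCircleError):
            circlerec.resolve_layout(evidence, min_support=3)
        layout = circlerec.resolve_layout(evidence, min_support=1)
        assert layout.n_segments == 2


class TestAssembleAndRotate:
    def test_single_segment_assembly(self, genome_5k):
        layout = CircleLayout((Segment(genome_5k.name, 1, 100),))
        circle = circlerec.assemble_circle(layout, genome_5k)
        assert circle.length == 100
        assert circle.sequence == genome_5k.sequence[:100]

    @given(
        starts=st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=4000),
                st.integers(min_value=60, max_value=900),
                st.sampled_from("+-"),
            ),
            min_size=1,
            max_size=4,
        )
    )
    def test_length_conservation_under_orientation(self, genome_5k, starts):
        elements = tuple(
            Segment(genome_5k.name, s, min(s + ln, 5000), strand)
            for s, ln, strand in starts
        )
        layout = CircleLayout(elements)
        circle = circlerec.assemble_circle(layout, genome_5k)
        assert circle.length == sum(seg.inclusive_length for seg in elements)

    def test_rotation_identity_and_example(self):
        circle = ReconstructedCircle(
            sequence="ACGTAG", layout=CircleLayout((Segment("c", 1, 6),))
        )
        assert rotate_to_anchor(circle, 1).sequence == "ACGTAG"
        assert rotate_to_anchor(circle, 3).sequence == "GTAGAC"

    def test_rotations_compose_modulo_length(self):
        circle = ReconstructedCircle(
            sequence="ACGTAGGT", layout=CircleLayout((Segment("c", 1, 8),))
        )
        once = rotate_to_anchor(rotate_to_anchor(circle, 4), 7)
        combined = rotate_to_anchor(circle, ((4 - 1) + (7 - 1)) % 8 + 1)
        assert once.sequence == combined.sequence

    def test_rotation_outside_circle_rejected(self):
        circle = ReconstructedCircle(
            sequence="ACGTAG", layout=CircleLayout((Segment("c", 1, 6),))
        )
        with pytest.raises(InvalidParameterError):
            rotate_to_anchor(circle, 7)

    def test_rotation_preserves_junction_set(self, scenario):
        """The set of adjacency-spanning 50-mers read off the circle sequence
        is invariant under rotation."""
        circle = ReconstructedCircle(
            sequence=scenario.circle.sequence, layout=scenario.circle.layout
        )

        def junction_kmers(seq, boundaries, k=25):
            doubled = seq + seq
            return {
                doubled[(b - k) % len(seq) : (b - k) % len(seq) + 2 * k]
                for b in boundaries
            }

        lengths = [seg.inclusive_length for seg in circle.layout.elements]
        boundaries = [lengths[0], 0]
        before = junction_kmers(circle.sequence, boundaries)
        rotated = rotate_to_anchor(circle, 12_345)
        shift = 12_345 - 1
        shifted_boundaries = [(b - shift) % circle.length for b in boundaries]
        after = junction_kmers(rotated.sequence, shifted_boundaries)
        assert before == after


class TestEndToEnd:
    def test_error_free_recovery_is_byte_exact(self):
        result = pipelines.run_end_to_end(seed=3)
        assert result["n_duplication_calls"] == 2
        assert result["byte_exact"]
        assert result["length_match"]

    def test_round_trip_junctions_regenerate_from_layout(self):
        result = pipelines.run_end_to_end(seed=4)
        layout = result["reconstructed"].layout
        scenario = result["scenario"]
        rebuilt = junctions.build_junctions(layout, scenario.genome)
        rebuilt_seqs = {_canonical(j.sequence) for j in rebuilt}
        supported = {
            _canonical(ev.candidate.junction_sequence)
            for ev in result["evidence"]
            if ev.supporting_reads >= 3
        }
        assert rebuilt_seqs == supported

    def test_noisy_reads_recover_layout(self):
        result = pipelines.run_end_to_end(seed=5, substitution_rate=0.02, max_edits=3)
        assert circular_equal(
            result["reconstructed"].sequence, result["scenario"].circle.sequence
        )
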
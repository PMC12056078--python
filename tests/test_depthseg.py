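"""Depth segmentation: normalization, calling, refinement, copy ratios."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from megatx import depthseg, simdata
from megatx.depthseg import DepthTrack, SegmentationParams
from megatx.errors import DegenerateTrackError
from megatx.intervals import Segment

from oracles import brute_force_segment_calls


def _track(depth, contig="chr"):
    return DepthTrack(contig=contig, depth=np.asarray(depth, dtype=float))


def _two_level_track(n=100_000, lo=802.0, hi=1765.0, start=40_000, end=70_000):
    depth = np.full(n, lo)
    depth[start:end] = hi
    return _track(depth)


class TestBinAndNormalize:
    def test_constant_depth_gives_unit_ratios(self):
        binned = depthseg.bin_and_normalize(_track(np.full(10_000, 100.0)), 1000)
        assert np.all(binned.ratios == 1.0)

    def test_event_bins_carry_depth_ratio(self):
        binned = depthseg.bin_and_normalize(_two_level_track(), 1000)
        inside = binned.ratios[40:70]
        assert np.allclose(inside, 1765.0 / 802.0)  # ~2.201
        assert round(float(inside[0]), 1) == 2.2

    def test_track_shorter_than_bin_is_single_unit_bin(self):
        binned = depthseg.bin_and_normalize(_track(np.full(300, 55.0)), 1000)
        assert binned.n_bins == 1
        assert binned.ratios[0] == 1.0

    def test_all_zero_track_is_degenerate(self):
        with pytest.raises(DegenerateTrackError):
            depthseg.bin_and_normalize(_track(np.zeros(5000)), 1000)


class TestCallSegments:
    def test_flat_track_yields_no_calls(self):
        binned = depthseg.bin_and_normalize(_track(np.full(50_000, 100.0)), 1000)
        assert depthseg.call_segments(binned) == []

    def test_recovers_simulated_duplication_within_one_bin(self):
        genome = simdata.generate_genome(400_000, 0.4, seed=1)
        truth = Segment(genome.name, 20_001, 60_000)
        track = simdata.simulate_depth_track(genome, [(truth, 2.2)], 100.0, seed=2)
        binned = depthseg.bin_and_normalize(track, 1000)
        calls = [c for c in depthseg.call_segments(binned) if c.kind == "duplication"]
        assert len(calls) == 1
        assert abs(calls[0].segment.start - truth.start) <= 1000
        assert abs(calls[0].segment.end - truth.end) <= 1000

    def test_recovery_rate_across_seeds(self):
        """Truth segments (depth >= 100, ratio 2.2, 40 bins) are recovered with
        boundary error <= 1 bin in at least 95% of 50 seeds."""
        genome = simdata.generate_genome(400_000, 0.4, seed=1)
        truth = Segment(genome.name, 20_001, 60_000)
        ok = 0
        for seed in range(50):
            track = simdata.simulate_depth_track(genome, [(truth, 2.2)], 100.0, seed=seed)
            binned = depthseg.bin_and_normalize(track, 1000)
            calls = [
                c for c in depthseg.call_segments(binned) if c.kind == "duplication"
            ]
            ok += (
                len(calls) == 1
                and abs(calls[0].segment.start - truth.start) <= 1000
                and abs(calls[0].segment.end - truth.end) <= 1000
            )
        assert ok >= 48  # 95% of 50, rounded up

    def test_gap_wider_than_max_gap_splits_calls(self):
        depth = np.full(100_000, 100.0)
        depth[20_000:35_000] = 220.0
        depth[45_000:60_000] = 220.0  # 10-bin gap > max_gap_bins = 5
        binned = depthseg.bin_and_normalize(_track(depth), 1000)
        calls = depthseg.call_segments(binned)
        assert [c.kind for c in calls] == ["duplication", "duplication"]

    def test_gap_within_max_gap_merges_calls(self):
        depth = np.full(100_000, 100.0)
        depth[20_000:35_000] = 220.0
        depth[38_000:55_000] = 220.0  # 3-bin gap <= max_gap_bins
        binned = depthseg.bin_and_normalize(_track(depth), 1000)
        calls = depthseg.call_segments(binned)
        assert len(calls) == 1
        assert calls[0].segment.start == 20_001
        assert calls[0].segment.end == 55_000

    def test_deletion_called_with_both_length_conventions(self):
        depth = np.full(60_000, 500.0)
        depth[30_000:32_000] = 0.0
        binned = depthseg.bin_and_normalize(_track(depth), 1000)
        calls = [c for c in depthseg.call_segments(binned) if c.kind == "deletion"]
        assert len(calls) == 1
        report = calls[0].report()
        assert report["inclusive_length"] == report["span"] + 1
        assert calls[0].copy_ratio == 0.0

    def test_matches_brute_force_oracle_on_random_tracks(self):
        params = SegmentationParams(min_dup_length=3000, min_del_length=2000)
        rng = np.random.default_rng(99)
        for _ in range(10):
            depth = rng.poisson(100, size=80_000).astype(float)
            # drop in a few random events
            for _ in range(int(rng.integers(0, 4))):
                s = int(rng.integers(0, 70_000))
                ln = int(rng.integers(1000, 15_000))
                ratio = float(rng.choice([0.0, 0.1, 2.0, 2.5, 3.0]))
                depth[s : s + ln] = rng.poisson(100 * ratio, size=min(ln, 80_000 - s))
            binned = depthseg.bin_and_normalize(_track(depth), 1000)
            got = {
                (c.kind, c.segment.start, c.segment.end)
                for c in depthseg.call_segments(binned, params)
            }
            expected = set()
            for kind, first, last in brute_force_segment_calls(
                binned.ratios, params.dup_threshold, params.del_threshold,
                params.max_gap_bins,
            ):
                seg = binned.bin_segment(first, last)
                min_len = (
                    params.min_dup_length if kind == "dup" else params.min_del_length
                )
                if seg.inclusive_length >= min_len:
                    expected.add(
                        (
                            "duplication" if kind == "dup" else "deletion",
                            seg.start,
                            seg.end,
                        )
                    )
            assert got == expected

    @given(scale=st.floats(min_value=0.05, max_value=50.0))
    def test_scale_invariance(self, scale):
        depth = np.full(40_000, 100.0)
        depth[10_000:25_000] = 230.0
        a = depthseg.call_segments(depthseg.bin_and_normalize(_track(depth), 1000))
        b = depthseg.call_segments(
            depthseg.bin_and_normalize(_track(depth * scale), 1000)
        )
        assert [(c.kind, c.segment, c.copy_ratio) for c in a] == [
            (c.kind, c.segment, c.copy_ratio) for c in b
        ]


class TestRefineBoundaries:
    def _call(self, segment):
        return depthseg.SegmentCall(
            segment=segment, kind="duplication", copy_ratio=2.2,
            mean_depth_inside=220.0, genome_median_depth=100.0,
        )

    def test_noiseless_step_refined_exactly(self):
        depth = np.full(60_000, 100.0)
        depth[50_000:] = 220.0  # step at base 50,001
        call = self._call(Segment("chr", 50_301, 60_000))
        refined = depthseg.refine_boundaries(call, _track(depth), 2000)
        assert refined.segment.start == 50_001

    def test_noisy_step_localized_within_25_bases(self):
        """At an 802x -> 1765x contrast the refined boundary lands within
        +/- 25 bp of the truth in at least 95% of 50 seeds."""
        ok = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            depth = np.concatenate(
                [rng.poisson(802.0, 10_000), rng.poisson(1765.0, 10_000)]
            ).astype(float)
            call = self._call(Segment("chr", 10_001 + int(rng.integers(-400, 400)), 20_000))
            refined = depthseg.refine_boundaries(call, _track(depth), 2000)
            ok += abs(refined.segment.start - 10_001) <= 25
        assert ok >= 48

    def test_step_at_track_edge_is_clamped(self):
        # the flanking windows cannot fit a 1.5 kb contig: warn, keep boundary
        depth = np.full(1500, 100.0)
        depth[500:] = 250.0
        call = self._call(Segment("chr", 400, 1500))
        with pytest.warns(UserWarning):
            refined = depthseg.refine_boundaries(call, _track(depth), 2000)
        assert refined.segment == call.segment

    def test_short_event_boundaries_keep_their_own_steps(self):
        # both edges of a short event sit inside one search range; the signed
        # step keeps each boundary on its own edge
        rng = np.random.default_rng(3)
        depth = rng.poisson(802.0, 12_000).astype(float)
        depth[5_430:7_869] = 0.0
        call = depthseg.SegmentCall(
            segment=Segment("chr", 6_001, 8_000), kind="deletion", copy_ratio=0.0,
            mean_depth_inside=0.0, genome_median_depth=802.0,
        )
        refined = depthseg.refine_boundaries(call, _track(depth), 2000)
        assert refined.segment.start == 5_431
        assert refined.segment.end == 7_868 + 1


class TestEstimateCopyRatio:
    def test_median_of_in_segment_bins(self):
        depth = np.concatenate(
            [np.full(10_000, 100.0), np.repeat([210.0, 220.0, 230.0], 1000),
             np.full(10_000, 100.0)]
        )
        binned = depthseg.bin_and_normalize(_track(depth), 1000)
        call = self._call(Segment("chr", 10_001, 13_000))
        assert depthseg.estimate_copy_ratio(call, binned) == 2.2

    def test_uniform_bins(self):
        depth = np.full(20_000, 100.0)
        depth[5_000:10_000] = 220.0
        binned = depthseg.bin_and_normalize(_track(depth), 1000)
        call = self._call(Segment("chr", 5_001, 10_000))
        assert depthseg.estimate_copy_ratio(call, binned) == 2.2

    def test_poisson_simulated_ratio_in_band(self):
        genome = simdata.generate_genome(200_000, 0.4, seed=5)
        truth = Segment(genome.name, 20_001, 60_000)
        track = simdata.simulate_depth_track(
            genome, [(truth, 1765.0 / 802.0)], 802.0, seed=6
        )
        binned = depthseg.bin_and_normalize(track, 1000)
        calls = [c for c in depthseg.call_segments(binned) if c.kind == "duplication"]
        assert len(calls) == 1
        assert 2.0 <= depthseg.estimate_copy_ratio(calls[0], binned) <= 2.4

    def _call(self, segment):
        return depthseg.SegmentCall(
            segment=segment, kind="duplication", copy_ratio=0.0,
            mean_depth_inside=0.0, genome_median_depth=1.0,
        )


class TestDepthTrackIO:
    def test_bedgraph_round_trip(self, tmp_path):
        depth = np.array([5.0, 5.0, 7.0, 0.0, 2.0])
        track = _track(depth)
        path = tmp_path / "t.bedgraph"
        track.to_bedgraph(path)
        again = DepthTrack.from_bedgraph(path)
        assert again.contig == track.contig
        assert np.array_equal(again.depth, depth)

    def test_tsv_round_trip(self, tmp_path):
        depth = np.array([1.0, 0.0, 3.5])
        path = tmp_path / "t.tsv"
        _track(depth).to_tsv(path)
        again = DepthTrack.from_tsv(path)
        assert np.array_equal(again.depth, depth)
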
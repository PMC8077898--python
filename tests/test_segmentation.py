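import numpy as np
import pytest

from cnvscape import (
    SegmentationParams,
    Segment,
    call_cnvs,
    permutation_pvalue,
    segment_chromosome,
)
from oracles import exhaustive_least_squares_breakpoints


def breakpoints_of(segments):
    return tuple(s.first for s in segments[1:])


class TestSegmentationParams:
    def test_defaults_valid(self):
        params = SegmentationParams()
        assert params.min_markers == 3
        assert params.n_permutations == 2000

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_markers": 1},
            {"p_cutoff": 0.0},
            {"p_cutoff": 1.5},
            {"n_permutations": 100, "p_cutoff": 0.005},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SegmentationParams(**kwargs)


class TestSegmentChromosome:
    def test_single_clean_step_found_exactly(self):
        values = np.r_[np.zeros(50), np.ones(50)]
        segments = segment_chromosome(values, SegmentationParams(seed=1))
        assert breakpoints_of(segments) == (50,)

    def test_constant_series_single_segment(self):
        segments = segment_chromosome(np.full(60, 0.3), SegmentationParams(seed=1))
        assert len(segments) == 1

    def test_two_marker_excursion_not_isolated(self):
        values = np.zeros(30)
        values[10:12] = 2.0
        segments = segment_chromosome(values, SegmentationParams(seed=1))
        assert len(segments) == 1

    def test_segments_tile_series_and_respect_minimum(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 0.15, 120)
        values[40:55] -= 0.45
        segments = segment_chromosome(values, SegmentationParams(seed=5))
        assert segments[0].first == 0
        assert segments[-1].last == len(values) - 1
        for a, b in zip(segments, segments[1:]):
            assert b.first == a.last + 1
        assert all(s.n_markers >= 3 for s in segments)

    def test_signal_conservation(self):
        rng = np.random.default_rng(6)
        values = rng.normal(0, 0.15, 150)
        values[100:120] += 0.5
        segments = segment_chromosome(values, SegmentationParams(seed=6))
        weighted = sum(s.mean_lrr * s.n_markers for s in segments) / len(values)
        assert weighted == pytest.approx(values.mean(), abs=1e-12)

    def test_short_series_returned_whole(self):
        segments = segment_chromosome(np.array([0.1, 5.0, 0.2]), SegmentationParams(seed=1))
        assert len(segments) == 1

    def test_determinism(self):
        rng = np.random.default_rng(7)
        values = rng.normal(0, 0.15, 200)
        values[50:70] -= 0.45
        a = segment_chromosome(values, SegmentationParams(seed=3))
        b = segment_chromosome(values, SegmentationParams(seed=3))
        assert a == b

    def test_noise_free_matches_exhaustive_least_squares_oracle(self):
        """Breakpoint recovery equals brute-force LS segmentation on clean steps.

        Blocks are at least 8 markers long: with 2000 permutations and a
        0.005 cutoff, a shorter block in a 30-marker series cannot reach
        significance for combinatorial reasons (too few distinguishable
        arrangements), which is a property of the stated test, not of the
        search.
        """
        params = SegmentationParams(seed=2)
        n, min_block = 30, 8
        cases = [(b1,) for b1 in range(min_block, n - min_block + 1)]
        cases += [
            (b1, b2)
            for b1 in range(min_block, n - 2 * min_block + 1)
            for b2 in range(b1 + min_block, n - min_block + 1)
        ]
        for pattern in ([0.0, 1.0, 2.0], [0.0, 1.0, 0.0]):
            for bounds in cases:
                edges = (0, *bounds, n)
                values = np.concatenate(
                    [
                        np.full(hi - lo, pattern[k % len(pattern)])
                        for k, (lo, hi) in enumerate(zip(edges, edges[1:]))
                    ]
                )
                oracle = exhaustive_least_squares_breakpoints(values, max_breakpoints=2)
                got = breakpoints_of(segment_chromosome(values, params))
                assert got == oracle, f"bounds={bounds}: {got} != {oracle}"


class TestPermutationPvalue:
    def test_identical_constant_sides_give_one(self):
        assert permutation_pvalue(np.full(5, 1.0), np.full(5, 1.0), 2000, 0) == 1.0

    def test_clean_separation_matches_exact_enumeration(self):
        # For 5 zeros vs 5 fives, only arrangements placing all fives on one
        # side reproduce the observed (infinite) statistic: 2 of the C(10,5)
        # = 252 equally likely left-sets, so E[p] = (1 + 2000*2/252)/2001.
        p = permutation_pvalue(np.zeros(5), np.full(5, 5.0), 2000, 1)
        assert p <= 2 / 126
        expected = (1 + 2000 * 2 / 252) / 2001
        assert p == pytest.approx(expected, rel=0.8)

    def test_longer_clean_separation_below_cutoff(self):
        p = permutation_pvalue(np.zeros(15), np.full(15, 5.0), 2000, 1)
        assert p < 0.005

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_p_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        p = permutation_pvalue(rng.normal(size=10), rng.normal(size=12), 500, seed)
        assert 0.0 < p <= 1.0


class TestCallCNVs:
    def _segment(self, first, last, mean, chrom="chr1"):
        return Segment(
            chrom=chrom, first=first, last=last, start=first * 10 + 1, end=last * 10 + 1,
            mean_lrr=mean,
        )

    def test_threshold_classification(self):
        segments = [
            self._segment(0, 9, -0.45),
            self._segment(10, 19, 0.02),
            self._segment(20, 29, 0.25),
        ]
        calls = call_cnvs(segments, "s1", "A")
        assert [c.state for c in calls] == ["loss", "gain"]

    def test_adjacent_same_state_segments_merge(self):
        segments = [self._segment(0, 9, 0.3), self._segment(10, 19, 0.5)]
        calls = call_cnvs(segments, "s1", "A")
        assert len(calls) == 1
        assert calls[0].state == "gain"
        assert calls[0].n_markers == 20
        assert calls[0].mean_lrr == pytest.approx(0.4)

    def test_non_adjacent_same_state_not_merged(self):
        segments = [
            self._segment(0, 9, 0.3),
            self._segment(10, 19, 0.0),
            self._segment(20, 29, 0.5),
        ]
        calls = call_cnvs(segments, "s1", "A")
        assert len(calls) == 2

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            call_cnvs([], loss_threshold=0.3, gain_threshold=0.2)

    def test_breakpoint_count_respects_cap(self):
        params = SegmentationParams(max_segments_per_10k=2, seed=0)
        rng = np.random.default_rng(8)
        values = rng.normal(0, 0.1, 60)
        values[10:20] += 3
        values[30:40] -= 3
        values[48:56] += 3
        segments = segment_chromosome(values, params)
        assert len(segments) - 1 <= params.breakpoint_cap(60)
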
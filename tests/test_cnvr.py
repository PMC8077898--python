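import math

import numpy as np
import pandas as pd
import pytest

from cnvscape import (
    buffalo_like_genome,
    compare_populations,
    filter_by_frequency,
    frequency_threshold,
    loss_gain_ratio,
    merge_cnvs_to_cnvrs,
    percentage,
    summarize,
)
from cnvscape.regions import CNVR, cnvrs_to_frame
from conftest import make_calls
from oracles import per_base_cnvrs, per_base_sharing, random_toy_calls


class TestMerge:
    def test_two_overlapping_losses_merge(self):
        calls = make_calls(
            [("A1", "P", "chr1", 100, 200, "loss"), ("A2", "P", "chr1", 150, 250, "loss")]
        )
        regions = merge_cnvs_to_cnvrs(calls)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.state, r.n_carriers) == (100, 250, "loss", 2)

    def test_isolated_single_sample_call_is_singleton(self):
        calls = make_calls([("A1", "P", "chr2", 500, 600, "gain")])
        (region,) = merge_cnvs_to_cnvrs(calls)
        assert region.singleton

    def test_gain_plus_loss_is_complex(self):
        calls = make_calls(
            [("A1", "P", "chr1", 100, 200, "gain"), ("A2", "P", "chr1", 180, 300, "loss")]
        )
        (region,) = merge_cnvs_to_cnvrs(calls)
        assert region.state == "complex"

    def test_bookended_intervals_do_not_merge(self):
        # 1-based inclusive: [100,200] and [201,300] share no base.
        calls = make_calls(
            [("A1", "P", "chr1", 100, 200, "loss"), ("A2", "P", "chr1", 201, 300, "loss")]
        )
        assert len(merge_cnvs_to_cnvrs(calls)) == 2

    def test_merge_is_idempotent(self):
        rng = np.random.default_rng(3)
        calls = pd.DataFrame(random_toy_calls(rng, ["P"], n_calls=40))
        regions = merge_cnvs_to_cnvrs(calls, population="P")
        frame = cnvrs_to_frame(regions).rename(columns={"population": "pop"})
        again = merge_cnvs_to_cnvrs(
            frame.assign(sample=frame["carriers"], state=frame["state"]),
            population="P",
        )
        assert [(r.chrom, r.start, r.end, r.state) for r in again] == [
            (r.chrom, r.start, r.end, r.state) for r in regions
        ]

    def test_invalid_interval_rejected(self):
        calls = make_calls([("A1", "P", "chr1", 300, 200, "loss")])
        with pytest.raises(ValueError, match="end < start"):
            merge_cnvs_to_cnvrs(calls)

    def test_mixed_population_input_rejected(self):
        calls = make_calls(
            [("A1", "P1", "chr1", 1, 10, "loss"), ("B1", "P2", "chr1", 1, 10, "loss")]
        )
        with pytest.raises(ValueError, match="one population"):
            merge_cnvs_to_cnvrs(calls)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            raw = random_toy_calls(rng, ["P"], n_calls=int(rng.integers(5, 50)))
            regions = merge_cnvs_to_cnvrs(pd.DataFrame(raw), population="P")
            expected = per_base_cnvrs(raw)
            got = [
                (r.chrom, r.start, r.end, r.state, r.carriers, r.singleton)
                for r in sorted(regions, key=lambda r: (r.chrom, r.start))
            ]
            want = [
                (e["chrom"], e["start"], e["end"], e["state"], e["carriers"], e["singleton"])
                for e in expected
            ]
            assert got == want


class TestFrequencyThreshold:
    @pytest.mark.parametrize(
        "n,expected", [(242, 12), (100, 5), (19, 2), (1, 2), (40, 2), (50, 3)]
    )
    def test_reproduces_carrier_minimums(self, n, expected):
        assert frequency_threshold(n) == expected

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction(self, fraction):
        with pytest.raises(ValueError):
            frequency_threshold(100, fraction)

    def test_boundary_inclusive_filtering(self):
        def region(carriers):
            return CNVR("P", "chr1", 1, 100, "loss", tuple(f"s{i}" for i in range(carriers)), carriers)

        regions = [region(12), region(11), region(2)]
        kept = filter_by_frequency(regions, 12)
        assert [r.n_carriers for r in kept] == [12]

    def test_all_singletons_removed(self):
        regions = [CNVR("P", "chr1", i * 1000, i * 1000 + 10, "loss", (f"s{i}",), 1) for i in range(5)]
        assert filter_by_frequency(regions, 2) == []

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        regions = merge_cnvs_to_cnvrs(
            pd.DataFrame(random_toy_calls(rng, ["P"], 45)), population="P"
        )
        counts = [len(filter_by_frequency(regions, t)) for t in range(1, 6)]
        assert counts == sorted(counts, reverse=True)


class TestSharing:
    def _region(self, pop, chrom, start, end, state="loss", carriers=2):
        return CNVR(pop, chrom, start, end, state, tuple(f"{pop}{i}" for i in range(carriers)), carriers)

    def test_identical_regions_common(self):
        result = compare_populations(
            {"P1": [self._region("P1", "chr1", 100, 200)], "P2": [self._region("P2", "chr1", 100, 200)]}
        )
        assert result.count("common_CNVR") == 2
        assert result.venn == {("P1", "P2"): 1}

    def test_half_overlap_of_shorter_is_common(self):
        result = compare_populations(
            {"P1": [self._region("P1", "chr1", 1, 1000)], "P2": [self._region("P2", "chr1", 501, 1500)]}
        )
        assert result.labels[("P1", 0)] == "common_CNVR"

    def test_sub_half_overlap_stays_population_private(self):
        # overlap 490 bp = 49% of the shorter (1000 bp) region
        result = compare_populations(
            {"P1": [self._region("P1", "chr1", 1, 1000)], "P2": [self._region("P2", "chr1", 511, 2000)]}
        )
        assert result.labels[("P1", 0)] == "pop_CNVR"
        assert result.labels[("P2", 0)] == "pop_CNVR"

    def test_non_redundant_span_is_union(self):
        result = compare_populations(
            {"P1": [self._region("P1", "chr1", 100, 1000)], "P2": [self._region("P2", "chr1", 500, 1400)]}
        )
        row = result.non_redundant.iloc[0]
        assert (row["start"], row["end"]) == (100, 1400)
        assert row["label"] == "common_CNVR"

    def test_invalid_overlap_fraction(self):
        with pytest.raises(ValueError):
            compare_populations({"P1": [], "P2": []}, overlap_fraction=0.0)

    def test_needs_two_populations(self):
        with pytest.raises(ValueError):
            compare_populations({"P1": []})

    def test_monotone_in_overlap_fraction(self):
        rng = np.random.default_rng(5)
        pop_sets = {
            pop: merge_cnvs_to_cnvrs(
                pd.DataFrame(random_toy_calls(rng, [pop], 25)), population=pop
            )
            for pop in ("P1", "P2")
        }
        counts = [
            compare_populations(pop_sets, f).count("common_CNVR")
            for f in (0.1, 0.3, 0.5, 0.8, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_matches_per_base_sharing_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            pop_sets = {}
            oracle_sets = {}
            for pop in ("P1", "P2", "P3"):
                raw = random_toy_calls(rng, [pop], n_calls=int(rng.integers(4, 25)))
                regions = merge_cnvs_to_cnvrs(pd.DataFrame(raw), population=pop)
                regions = sorted(regions, key=lambda r: (r.chrom, r.start))
                pop_sets[pop] = regions
                oracle_sets[pop] = [
                    {"chrom": r.chrom, "start": r.start, "end": r.end} for r in regions
                ]
            got = compare_populations(pop_sets).labels
            want = per_base_sharing(oracle_sets)
            assert got == want


class TestSummaries:
    def test_printed_count_arithmetic(self):
        assert loss_gain_ratio(3528, 2887) == 1.22
        assert loss_gain_ratio(1399, 1343) == 1.04
        assert loss_gain_ratio(227, 166) == 1.37
        assert percentage(206.18, 2478.74) == 8.32
        assert percentage(109.60, 2478.74) == 4.42
        assert percentage(26.59, 2478.74) == 1.07
        assert percentage(834, 1678) == 49.7
        assert percentage(188, 257) == 73.15

    def test_zero_gain_ratio_is_missing_with_warning(self):
        with pytest.warns(UserWarning, match="zero gain"):
            assert math.isnan(loss_gain_ratio(10, 0))

    def test_summarize_counts_and_coverage(self):
        genome = buffalo_like_genome()
        calls = make_calls(
            [
                ("A1", "P", "chr1", 1, 7_500, "loss"),
                ("A2", "P", "chr1", 5_000, 20_000, "gain"),
                ("A1", "P", "chr2", 1_000_000, 1_200_000, "loss"),
            ]
        )
        regions = merge_cnvs_to_cnvrs(calls, population="P")
        stats = summarize(calls, {"P": regions}, genome, pop_sizes={"P": 4})["P"]
        assert stats.n_cnv == 3
        assert (stats.n_loss, stats.n_gain) == (2, 1)
        assert stats.loss_gain_ratio == 2.0
        assert stats.mean_cnv_per_sample == 0.75
        assert stats.n_cnvr == 2
        assert stats.n_singleton == 1
        assert stats.coverage_mb == round((20_000 + 200_001) / 1e6, 2)
        # one call in each of <10kb, 10-50kb, 100-500kb
        assert stats.length_class_proportions["<10kb"] == pytest.approx(1 / 3)
        assert stats.length_class_proportions["10-50kb"] == pytest.approx(1 / 3)
        assert stats.length_class_proportions["100-500kb"] == pytest.approx(1 / 3)
        assert sum(stats.length_class_proportions.values()) == pytest.approx(1.0)

    def test_single_small_cnv_fully_in_first_length_class(self):
        genome = buffalo_like_genome()
        calls = make_calls([("A1", "P", "chr1", 1_001, 8_500, "loss")])
        regions = merge_cnvs_to_cnvrs(calls, population="P")
        stats = summarize(calls, {"P": regions}, genome)["P"]
        assert stats.length_class_proportions["<10kb"] == 1.0
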
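import numpy as np
import pandas as pd
import pytest

from cnvscape import (
    GenomeModel,
    NoiseModel,
    TrueCNVR,
    buffalo_like_genome,
    build_marker_map,
    random_truth_set,
    simulate_cohort,
    simulate_snp_genotypes,
)
from cnvscape.popstruct import weir_cockerham_fst


class TestGenomeModel:
    def test_default_genome_totals(self):
        genome = buffalo_like_genome()
        assert genome.n_autosomes == 24
        assert genome.total_length == 2_478_740_000
        assert all(length > 0 for length in genome.chrom_lengths.values())

    def test_rejects_non_positive_chromosome(self):
        with pytest.raises(ValueError):
            GenomeModel({"chr1": 0})


class TestMarkerMap:
    def test_equal_chromosomes_split_markers_evenly(self):
        genome = GenomeModel({"chr1": 1_000_000, "chr2": 1_000_000})
        mm = build_marker_map(genome, 10, seed=0)
        assert mm["chrom"].value_counts().tolist() == [5, 5]

    def test_total_marker_count_and_proportionality(self):
        genome = buffalo_like_genome()
        mm = build_marker_map(genome, 70_230, seed=0)
        assert len(mm) == 70_230
        counts = mm.groupby("chrom", observed=True).size()
        expect = {
            c: 70_230 * length / genome.total_length
            for c, length in genome.chrom_lengths.items()
        }
        for chrom, count in counts.items():
            assert abs(count - expect[str(chrom)]) <= 1

    def test_sorted_unique_positions_and_gc_range(self, small_map):
        for _, group in small_map.groupby("chrom", observed=True):
            pos = group["pos"].to_numpy()
            assert (np.diff(pos) > 0).all()
        assert small_map["gc"].between(0, 1).all()

    def test_same_seed_reproduces_map(self, small_genome):
        a = build_marker_map(small_genome, 200, seed=5)
        b = build_marker_map(small_genome, 200, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_marker_count(self, small_genome):
        with pytest.raises(ValueError):
            build_marker_map(small_genome, 0)
        with pytest.raises(ValueError):
            build_marker_map(small_genome, 5)  # fewer than 3 per chromosome


class TestSimulateCohort:
    def test_full_penetrance_loss_region(self, small_map):
        pos = small_map.loc[small_map["chrom"] == "chr1", "pos"].to_numpy()
        region = TrueCNVR("chr1", int(pos[10]), int(pos[29]), {"A": 1.0}, "loss")
        cohort = simulate_cohort(
            small_map,
            [region],
            {"A": 10},
            NoiseModel(lrr_sd=0.15, gc_coeff_sd=0.0),
            seed=3,
            extreme_copy_prob=0.0,
        )
        assert len(cohort.truth) == 10
        in_region = (
            (small_map["chrom"] == "chr1")
            & small_map["pos"].between(region.start, region.end)
        ).to_numpy()
        values = cohort.lrr.to_numpy()[in_region]
        se = 0.15 / np.sqrt(values.size)
        assert abs(values.mean() - (-0.45)) < 3 * se

    def test_zero_frequency_gives_empty_truth_and_zero_mean(self, small_map):
        region = TrueCNVR("chr1", 1, 2_000_000, {"A": 0.0}, "gain")
        cohort = simulate_cohort(
            small_map, [region], {"A": 8}, NoiseModel(gc_coeff_sd=0.0), seed=4
        )
        assert cohort.truth.empty
        assert abs(cohort.lrr.to_numpy().mean()) < 0.01

    def test_zero_gc_coefficient_means_no_gc_slope(self, small_map):
        cohort = simulate_cohort(
            small_map, [], {"A": 6}, NoiseModel(gc_coeff_sd=0.0), seed=5
        )
        gc = small_map["gc"].to_numpy()
        pooled = cohort.lrr.to_numpy().mean(axis=1)
        slope = np.polyfit(gc - gc.mean(), pooled, 1)[0]
        assert abs(slope) < 0.2  # consistent with pure noise

    def test_truth_events_lie_inside_their_region(self, two_pop_cohort):
        small_map, truth, cohort = two_pop_cohort
        for ev in cohort.truth.itertuples(index=False):
            hits = [
                r
                for r in truth
                if r.chrom == ev.chrom and r.start <= ev.start and ev.end <= r.end
            ]
            assert len(hits) == 1

    def test_region_spanning_too_few_markers_rejected(self, small_map):
        pos = small_map.loc[small_map["chrom"] == "chr1", "pos"].to_numpy()
        thin = TrueCNVR("chr1", int(pos[5]), int(pos[6]), {"A": 0.5}, "loss")
        with pytest.raises(ValueError, match="at least 3"):
            simulate_cohort(small_map, [thin], {"A": 5}, seed=0)

    def test_same_seed_reproduces_cohort(self, small_map):
        truth = random_truth_set(small_map, 3, ["A"], seed=1)
        a = simulate_cohort(small_map, truth, {"A": 5}, seed=9)
        b = simulate_cohort(small_map, truth, {"A": 5}, seed=9)
        pd.testing.assert_frame_equal(a.lrr, b.lrr)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_shift_map_must_increase_with_copy_number(self):
        with pytest.raises(ValueError):
            NoiseModel(shifts={0: -3.0, 1: 0.5, 2: 0.0, 3: 0.3, 4: 0.58})


class TestRandomTruthSet:
    def test_regions_non_overlapping_within_chromosome(self, small_map):
        regions = random_truth_set(small_map, 9, ["A", "B"], seed=2)
        assert len(regions) == 9
        by_chrom: dict = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for rs in by_chrom.values():
            rs.sort(key=lambda r: r.start)
            for a, b in zip(rs, rs[1:]):
                assert a.end < b.start


class TestSNPGenotypes:
    def test_no_divergence_shares_frequencies(self):
        snp = simulate_snp_genotypes(2000, {"A": 150, "B": 150}, fst=0.0, seed=8)
        G = snp.genotypes.to_numpy(dtype=float)
        labels = snp.populations.to_numpy()
        p_a = G[labels == "A"].mean(axis=0) / 2
        p_b = G[labels == "B"].mean(axis=0) / 2
        # binomial sampling noise only: sd of the difference ~ sqrt(2 p q / 2n)
        diffs = p_a - p_b
        assert abs(diffs.mean()) < 0.005
        assert np.std(diffs) < 0.06

    def test_divergence_recovered_by_estimator(self):
        snp = simulate_snp_genotypes(5000, {"A": 100, "B": 100}, fst=0.05, seed=9)
        est = weir_cockerham_fst(snp.genotypes, snp.populations)
        assert abs(est - 0.05) < 0.01

    def test_same_seed_identical_matrix(self):
        a = simulate_snp_genotypes(200, {"A": 10}, fst=0.1, seed=3)
        b = simulate_snp_genotypes(200, {"A": 10}, fst=0.1, seed=3)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)

    @pytest.mark.parametrize("bad", [-0.1, 1.0])
    def test_invalid_fst_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_snp_genotypes(200, {"A": 10}, fst=bad)
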
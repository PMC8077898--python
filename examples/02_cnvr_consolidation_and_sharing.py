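"""Consolidate per-sample CNV calls into CNVRs and classify sharing.

Uses a hand-written call table so the merge rules are visible: >= 1 bp
overlap merges calls within a population; regions from different
populations sharing >= 50% of the shorter region become common_CNVRs.
"""

import pandas as pd

from cnvscape import (
    buffalo_like_genome,
    compare_populations,
    filter_by_frequency,
    frequency_threshold,
    merge_cnvs_to_cnvrs,
    summarize,
)

calls = pd.DataFrame(
    [
        # population P1: three overlapping losses and one singleton gain
        ("a1", "P1", "chr1", 10_000, 60_000, "loss"),
        ("a2", "P1", "chr1", 40_000, 90_000, "loss"),
        ("a3", "P1", "chr1", 55_000, 80_000, "loss"),
        ("a4", "P1", "chr2", 500_000, 620_000, "gain"),
        # population P2: a region overlapping P1's cluster plus a gain+loss pair
        ("b1", "P2", "chr1", 30_000, 70_000, "loss"),
        ("b2", "P2", "chr1", 35_000, 75_000, "loss"),
        ("b3", "P2", "chr3", 100_000, 180_000, "gain"),
        ("b4", "P2", "chr3", 150_000, 230_000, "loss"),
    ],
    columns=["sample", "population", "chrom", "start", "end", "state"],
)

pop_sets = {}
for pop in ("P1", "P2"):
    regions = merge_cnvs_to_cnvrs(calls[calls["population"] == pop], population=pop)
    threshold = frequency_threshold(n_samples=20)  # 5% of 20 samples, floor 2
    pop_sets[pop] = filter_by_frequency(regions, threshold)
    for r in regions:
        flag = " (singleton)" if r.singleton else ""
        print(f"{pop}: {r.chrom}:{r.start}-{r.end} {r.state}, "
              f"{r.n_carriers} carrier(s){flag}")

sharing = compare_populations(pop_sets)
print("\nsharing labels:", sharing.venn)
print(sharing.non_redundant[["chrom", "start", "end", "state", "label", "populations"]])

stats = summarize(calls, pop_sets, buffalo_like_genome(),
                  pop_sizes={"P1": 20, "P2": 20})
for pop, s in stats.items():
    print(f"\n{pop}: {s.n_cnv} CNVs, loss/gain ratio {s.loss_gain_ratio}, "
          f"coverage {s.coverage_mb} Mb ({s.coverage_pct}% of autosomes)")
# The chr1 clusters of P1 and P2 overlap by more than half of the shorter
# region, so they form one common_CNVR; the chr3 gain+loss cluster is a
# complex region private to P2.
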